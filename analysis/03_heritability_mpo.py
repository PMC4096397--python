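#!/usr/bin/env python
"""Mid-parent-offspring heritability of CpG methylation.

Regresses each child's methylation on the parental mean across the 52
trios, calls heritable CpGs (h2 > 0.2, >= 10 trios, BH q < 0.05), splits
them into SNP-CpGs vs non-SNP CpGs, and clusters adjacent heritable
non-SNP sites. Compares the calls against the simulation ground truth.
"""

from pathlib import Path

import pandas as pd

from pedmeth import io as pio
from pedmeth.config import AnalysisConfig
from pedmeth.mpo import run_mpo
from pedmeth.pipeline import load_study

ROOT = Path(__file__).resolve().parents[1]
COHORT = ROOT / "results" / "cohort"
OUT = ROOT / "results"


def main() -> None:
    study = load_study(COHORT / "genotypes.vcf", COHORT / "pedigree.fam",
                       OUT / "methylation_filtered.tsv")
    truth = pio.read_truth_json(COHORT / "truth.json")
    config = AnalysisConfig()

    res, clusters = run_mpo(study.methylation, study.pedigree.trios(),
                            study.genotypes, h2_min=config.h2_min,
                            min_trios=config.min_trios, fdr=config.fdr)
    res.to_csv(OUT / "mpo_results.tsv", sep="\t", index=False)
    clusters.to_csv(OUT / "mpo_clusters.tsv", sep="\t", index=False)

    n_her = int(res["heritable"].sum())
    n_snp = int((res["heritable"] & res["snp_cpg"]).sum())
    print(f"{n_her} heritable CpGs of {len(res)} analyzed "
          f"({n_snp} SNP-CpGs, {n_her - n_snp} non-SNP)")
    print(f"{len(clusters)} clusters of adjacent heritable non-SNP CpGs")

    truth_cls = truth.cpg_class.set_index("pos")["class"]
    called = res.loc[res["heritable"], "pos"]
    by_class = truth_cls.loc[called].value_counts()
    print("heritable calls by true class:")
    print(by_class.to_string())


if __name__ == "__main__":
    main()
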