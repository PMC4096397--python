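#!/usr/bin/env python
"""Cross-method comparison and region enrichment.

Overlaps the CpG sets called by the MPO, mQTL and ASM analyses, and
computes enrichment of the heritable CpGs across genomic region labels
from a demo BED annotation generated alongside the cohort.
"""

from pathlib import Path

import pandas as pd

from pedmeth.compare import (annotate_enrichment, comparison_report,
                             overlap_fractions)
from pedmeth.config import AnalysisConfig

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results"


def demo_regions(cpg_positions) -> pd.DataFrame:
    """Alternating promoter / gene-body intervals tiling the CpG span."""
    lo, hi = min(cpg_positions) - 1, max(cpg_positions)
    width = max((hi - lo) // 8, 1)
    rows = []
    for k in range(8):
        label = "promoter" if k % 2 == 0 else "gene_body"
        rows.append(("chr1", lo + k * width, lo + (k + 1) * width, label))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "label"])


def main() -> None:
    config = AnalysisConfig()
    mpo = pd.read_csv(OUT / "mpo_results.tsv", sep="\t")
    mqtl = pd.read_csv(OUT / "mqtl_results.tsv", sep="\t")
    asm = pd.read_csv(OUT / "asm_merged.tsv", sep="\t")

    report = comparison_report(mpo, mqtl, asm, fdr=config.fdr)
    report.to_csv(OUT / "comparison.tsv", sep="\t", index=False)
    print(report.to_string(index=False))

    her_nonsnp = set(zip(mpo.loc[mpo["heritable"] & ~mpo["snp_cpg"], "chrom"],
                         mpo.loc[mpo["heritable"] & ~mpo["snp_cpg"], "pos"]))
    sig_mqtl = mqtl[mqtl["q"] < config.fdr]
    mqtl_nonsnp = set(zip(sig_mqtl["chrom"], sig_mqtl["cpg_pos"])) - set(
        zip(mpo.loc[mpo["snp_cpg"], "chrom"], mpo.loc[mpo["snp_cpg"], "pos"]))
    if mqtl_nonsnp:
        ov = overlap_fractions(mqtl_nonsnp, her_nonsnp)
        print(f"\n{100 * ov.frac_a_in_b:.1f}% of non-SNP CpGs with a cis "
              "mQTL are also heritable by the trio analysis "
              f"({ov.n_intersection}/{ov.n_a})")

    heritable = set(zip(mpo.loc[mpo["heritable"], "chrom"],
                        mpo.loc[mpo["heritable"], "pos"]))
    background = set(zip(mpo["chrom"], mpo["pos"]))
    if heritable:
        regions = demo_regions(mpo["pos"])
        enrich = annotate_enrichment(heritable, background, regions)
        enrich.to_csv(OUT / "enrichment.tsv", sep="\t", index=False)
        print("\nregion enrichment of heritable CpGs:")
        print(enrich.to_string(index=False))


if __name__ == "__main__":
    main()
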