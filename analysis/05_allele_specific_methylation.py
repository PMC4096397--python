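#!/usr/bin/env python
"""Allele-specific methylation from allele-tagged fragments.

Builds one 2x2 (allele x methylation) table per (sample, SNP, CpG), calls
ASM where Fisher's exact p < 0.001 and the between-allele methylation
difference exceeds 0.2, and merges events across individuals.
"""

from pathlib import Path

from pedmeth import io as pio
from pedmeth.asm import call_asm, merge_asm_events
from pedmeth.config import AnalysisConfig
from pedmeth.pipeline import load_study

ROOT = Path(__file__).resolve().parents[1]
COHORT = ROOT / "results" / "cohort"
OUT = ROOT / "results"


def main() -> None:
    study = load_study(COHORT / "genotypes.vcf", COHORT / "pedigree.fam",
                       COHORT / "methylation.tsv",
                       frags_path=COHORT / "fragments.tsv")
    config = AnalysisConfig()

    events = call_asm(study.fragments, p_max=config.asm_p_max,
                      delta_min=config.asm_delta_min,
                      min_per_allele=config.asm_min_per_allele,
                      genotypes=study.genotypes)
    merged = merge_asm_events(events)
    events.to_csv(OUT / "asm_events.tsv", sep="\t", index=False)
    merged.to_csv(OUT / "asm_merged.tsv", sep="\t", index=False)

    n_tables = study.fragments.records.groupby(
        ["sample_id", "snp_id", "cpg_pos"]).ngroups
    print(f"{len(events)} ASM events from {n_tables} testable tables "
          f"across {events['sample_id'].nunique() if len(events) else 0} "
          "samples")
    if len(merged):
        n_snp_cpg = int(merged["snp_cpg"].sum())
        multi = merged[merged["support"] >= 2]
        print(f"{len(merged)} merged ASM CpGs ({n_snp_cpg} SNP-CpGs); "
              f"{len(multi)} supported by 2+ individuals, "
              f"{int(multi['direction_consistent'].sum())} of those "
              "direction-consistent")


if __name__ == "__main__":
    main()
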