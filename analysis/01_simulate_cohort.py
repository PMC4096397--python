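#!/usr/bin/env python
"""Simulate the study cohort: 22 nuclear families, 96 samples, 52 trios.

Plants every effect class the downstream analyses look for — SNP-CpGs
(dinucleotide-destroying variants), cis mean-shift mQTLs, one vSNP variance
block, and family-shared non-genetic noise — and writes the study files
(VCF, FAM, methylation TSV, fragment TSV) plus the ground-truth sidecar
under results/cohort/.
"""

from pathlib import Path

from pedmeth import io as pio
from pedmeth.pipeline import Study, write_study
from pedmeth.synthetic import (DEFAULT_FAMILY_CHILD_COUNTS, EffectConfig,
                               simulate_allelic_fragments, simulate_cohort,
                               simulate_methylome)

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results" / "cohort"

SEED = 20240901

EFFECT = EffectConfig(
    n_snps=30, n_cpgs=80, seed=SEED, read_depth=80,
    chrom_length=50_000_000, maf_range=(0.25, 0.5),
    snp_cpg_sites=[(0, 0), (1, 1), (2, 2)],
    cis_effects=[(3, 10, 0.25), (4, 12, -0.22), (5, 14, 0.2)],
    vsnp_effects=[(6, tuple(range(30, 38)), 0.02, 0.08, 0.15)],
    family_noise_cpgs=[50, 51, 52, 53], family_noise_sd=0.15,
)


def main() -> None:
    pedigree, genotypes = simulate_cohort(22, DEFAULT_FAMILY_CHILD_COUNTS,
                                          EFFECT)
    meth, truth = simulate_methylome(pedigree, genotypes, EFFECT)
    frags = simulate_allelic_fragments(genotypes, truth, depth=40, seed=SEED)

    OUT.mkdir(parents=True, exist_ok=True)
    write_study(Study(pedigree, genotypes, meth, frags), OUT)
    pio.write_truth_json(truth, OUT / "truth.json")

    trios = pedigree.trios()
    print(f"cohort: {len(pedigree.sample_ids)} samples in "
          f"{len(pedigree.families())} families ({len(trios)} trios)")
    print(f"genotypes: {genotypes.n_snps} SNPs; methylome: {meth.n_sites} "
          f"CpGs; fragments: {len(frags)} allele-tagged records")
    print(f"planted: {len(truth.snp_cpg_pairs)} SNP-CpGs, "
          f"{len(truth.cis_pairs)} cis effects, "
          f"{len(truth.vsnp_blocks)} vSNP block, "
          f"{len(truth.family_noise_positions)} family-noise CpGs")
    print(f"written to {OUT}")


if __name__ == "__main__":
    main()
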