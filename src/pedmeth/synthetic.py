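"""Synthetic pedigree-methylome cohorts with known ground truth.

Emulates the structure of a targeted-bisulfite family study — nuclear
pedigrees (two founder parents, one or more children), biallelic SNP
genotypes, and a CpG methylation fraction matrix with read-depth noise —
while planting three kinds of genetic signal whose coordinates are recorded
for parameter-recovery tests:

* **SNP-CpG** sites: a SNP destroys the CpG dinucleotide, so each alt
  allele contributes zero methylation (observed = latent * (2 - dosage)/2).
* **cis effects**: a nearby SNP shifts mean methylation additively per alt
  allele.
* **vSNP effects**: a SNP modulates the residual *variance* of methylation
  over a block of adjacent CpGs (one residual SD per genotype class).

A fourth, non-genetic signal class — family-shared noise drawn once per
family per CpG — gives the mid-parent-offspring analysis a positive control
that no SNP-based method should detect.

All randomness flows through per-stage `numpy` Generator streams derived
from ``EffectConfig.seed``, so a cohort is bit-reproducible and adding CpGs
does not perturb genotype draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import (AllelicFragmentSet, GenotypeMatrix, MethylationMatrix,
                         PedigreeSet)

_STAGE_CODES = {"layout": 1, "pedigree": 2, "genotypes": 3,
                "methylome": 4, "fragments": 5, "maf": 6}


def _rng(seed: int, stage: str) -> np.random.Generator:
    """One independent stream per (stage, seed)."""
    return np.random.default_rng(np.random.SeedSequence([seed, _STAGE_CODES[stage]]))


# 22 nuclear families, 44 founder parents + 52 children = 96 samples,
# hence 52 parent-child trios — the cohort structure every default emulates.
DEFAULT_FAMILY_CHILD_COUNTS: tuple[int, ...] = (3,) * 8 + (2,) * 14


@dataclass
class EffectConfig:
    """Generative layout of SNPs, CpGs and planted effects.

    SNPs and CpGs are referenced by logical index (0-based, in genomic
    order). ``snp_cpg_sites`` are (snp, cpg) pairs where the SNP destroys
    the dinucleotide; ``cis_effects`` are (snp, cpg, beta-per-alt-allele);
    ``vsnp_effects`` are (snp, (cpg, ...), sigma0, sigma1, sigma2) with one
    residual SD per genotype class and block members at consecutive logical
    indices. ``read_depth`` is the mean of the per-cell Poisson depth;
    ``None`` selects infinite-depth mode (observed == latent, no binomial
    sampling).
    """

    n_snps: int = 20
    n_cpgs: int = 50
    chrom_length: int = 50_000_000
    chrom: str = "chr1"
    maf_range: tuple[float, float] = (0.1, 0.5)
    baseline_beta: tuple[float, float] = (2.0, 2.0)
    snp_cpg_sites: list[tuple[int, int]] = field(default_factory=list)
    cis_effects: list[tuple[int, int, float]] = field(default_factory=list)
    vsnp_effects: list[tuple[int, tuple, float, float, float]] = field(
        default_factory=list)
    family_noise_cpgs: list[int] = field(default_factory=list)
    family_noise_sd: float = 0.1
    # across-sample biological noise; the default makes unplanted CpGs
    # "variable" sites (SD >= 0.1) like the ones the analyses operate on
    residual_sd: float = 0.15
    vsnp_block_spacing: int = 100
    cis_max_offset: int = 50_000
    read_depth: float | None = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must lie in (0, 0.5], got {self.maf_range}")
        if self.family_noise_sd < 0 or self.residual_sd < 0:
            raise ValueError("noise SDs must be non-negative")
        used_snps: set[int] = set()
        for snp, cpg in self.snp_cpg_sites:
            self._check_pair(snp, cpg, used_snps)
        for snp, cpg, beta in self.cis_effects:
            self._check_pair(snp, cpg, used_snps)
        for snp, cpgs, *sigmas in self.vsnp_effects:
            for cpg in cpgs:
                self._check_pair(snp, cpg, used_snps - {snp})
            used_snps.add(snp)
            if any(s < 0 for s in sigmas):
                raise ValueError("vSNP sigmas must be non-negative")
            idx = list(cpgs)
            if idx != list(range(idx[0], idx[0] + len(idx))):
                raise ValueError("vSNP block CpGs must be consecutive logical "
                                 f"indices, got {idx}")

    def _check_pair(self, snp: int, cpg: int, used: set[int]) -> None:
        if not 0 <= snp < self.n_snps:
            raise ValueError(f"effect references unknown SNP index {snp}")
        if not 0 <= cpg < self.n_cpgs:
            raise ValueError(f"effect references unknown CpG index {cpg}")
        if snp in used:
            raise ValueError(f"SNP {snp} assigned to more than one effect role")
        used.add(snp)


@dataclass
class CohortTruth:
    """Ground-truth effect coordinates for parameter-recovery tests."""

    cpg_class: pd.DataFrame           # chrom, pos, class
    snp_cpg_pairs: list[tuple[str, int]]          # (snp_id, cpg pos)
    cis_pairs: list[tuple[str, int, float]]       # (snp_id, cpg pos, beta)
    vsnp_blocks: list[dict]           # snp_id, cpg_positions, sigmas
    family_noise_positions: list[int]
    baseline: np.ndarray              # per-CpG baseline methylation
    allele_meth_probs: dict           # (snp_id, cpg pos) -> (p_ref, p_alt)


def _layout(effect: EffectConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Deterministic genomic coordinates for CpGs and SNPs.

    CpGs occupy jittered, evenly spaced slots so logical index equals
    genomic order; vSNP-block members are re-laid at
    ``vsnp_block_spacing`` bp. Effect SNPs are co-located with their target
    CpG (exactly on the dinucleotide for SNP-CpGs, within
    ``cis_max_offset`` otherwise); background SNPs land uniformly but never
    on a CpG dinucleotide, so SNP-CpG truth is exact.
    """
    rng = _rng(effect.seed, "layout")
    n_cpgs, n_snps = effect.n_cpgs, effect.n_snps
    slot = effect.chrom_length // max(n_cpgs, 1)
    block_span = max((len(cpgs) * effect.vsnp_block_spacing
                      for _, cpgs, *_ in effect.vsnp_effects), default=0)
    if n_cpgs and slot <= 2 * (block_span + 10):
        raise ValueError("chrom_length too small for the requested CpG count "
                         "and vSNP block span")
    jitter = max(slot // 4, 1)
    cpg_pos = np.array([(j * slot) + slot // 2 + int(rng.integers(-jitter, jitter + 1))
                        for j in range(n_cpgs)], dtype=int)
    cpg_pos = np.maximum(cpg_pos, 1)
    for _, cpgs, *_ in effect.vsnp_effects:
        first = cpgs[0]
        for k, cpg in enumerate(cpgs):
            cpg_pos[cpg] = cpg_pos[first] + k * effect.vsnp_block_spacing

    forbidden = set(cpg_pos) | set(cpg_pos + 1)  # the C and the G
    snp_pos = np.zeros(n_snps, dtype=int)
    placed = np.zeros(n_snps, dtype=bool)
    for snp, cpg in effect.snp_cpg_sites:
        snp_pos[snp] = int(cpg_pos[cpg]) + int(rng.integers(0, 2))
        placed[snp] = True
    for snp, cpg, _beta in effect.cis_effects:
        snp_pos[snp] = _offset_pos(rng, int(cpg_pos[cpg]), effect, forbidden)
        placed[snp] = True
    for snp, cpgs, *_ in effect.vsnp_effects:
        snp_pos[snp] = _offset_pos(rng, int(cpg_pos[cpgs[0]]), effect, forbidden)
        placed[snp] = True
    for snp in np.flatnonzero(~placed):
        while True:
            p = int(rng.integers(1, effect.chrom_length + 1))
            if p not in forbidden:
                snp_pos[snp] = p
                break

    cpg_sites = pd.DataFrame({"chrom": effect.chrom, "pos": cpg_pos,
                              "strand": "+"})
    snps = pd.DataFrame({"id": [f"snp{i}" for i in range(n_snps)],
                         "chrom": effect.chrom, "pos": snp_pos,
                         "ref": "A", "alt": "G"})
    snps = snps.sort_values("pos", kind="stable").reset_index(drop=True)
    return cpg_sites, snps


def _offset_pos(rng, anchor: int, effect: EffectConfig, forbidden: set) -> int:
    for _ in range(1000):
        off = int(rng.integers(-effect.cis_max_offset, effect.cis_max_offset + 1))
        p = max(anchor + off, 1)
        if p not in forbidden:
            return p
    raise RuntimeError("could not place effect SNP off the CpG dinucleotides")


def _mafs(effect: EffectConfig) -> np.ndarray:
    rng = _rng(effect.seed, "maf")
    lo, hi = effect.maf_range
    return rng.uniform(lo, hi, size=effect.n_snps)


def simulate_cohort(n_families: int,
                    children_per_family: int | tuple[int, int],
                    effect: EffectConfig) -> tuple[PedigreeSet, GenotypeMatrix]:
    """Simulate nuclear pedigrees and Mendelian genotypes.

    Founders are drawn in Hardy-Weinberg proportions at each SNP's minor
    allele frequency; each child inherits one allele per parent, chosen
    uniformly, so simulated trios are Mendel-error free by construction.
    """
    if n_families < 0:
        raise ValueError("n_families must be >= 0")
    ped_rng = _rng(effect.seed, "pedigree")
    rows = []
    for i in range(n_families):
        fam = f"fam{i:03d}"
        father, mother = f"{fam}_f", f"{fam}_m"
        rows.append((father, fam, None, None, 1))
        rows.append((mother, fam, None, None, 2))
        if isinstance(children_per_family, int):
            k = children_per_family
        elif len(children_per_family) == 2 and isinstance(children_per_family, tuple):
            lo, hi = children_per_family
            k = int(ped_rng.integers(lo, hi + 1))
        else:  # explicit per-family counts
            k = int(children_per_family[i % len(children_per_family)])
        for c in range(k):
            sex = int(ped_rng.integers(1, 3))
            rows.append((f"{fam}_c{c}", fam, father, mother, sex))
    pedigree = PedigreeSet(pd.DataFrame(
        rows, columns=["sample_id", "family_id", "father_id", "mother_id", "sex"]))

    cpg_sites, snps = _layout(effect)
    maf_by_logical = _mafs(effect)
    logical = snps["id"].str.removeprefix("snp").astype(int).to_numpy()
    maf = maf_by_logical[logical]

    gt_rng = _rng(effect.seed, "genotypes")
    samples = pedigree.sample_ids
    n_snps = len(snps)
    dosages = np.zeros((n_snps, len(samples)))
    col = {s: j for j, s in enumerate(samples)}
    for s in pedigree.founders():
        dosages[:, col[s]] = gt_rng.binomial(2, maf)
    for f, m, c in pedigree.trios():
        a_f = gt_rng.random(n_snps) < dosages[:, col[f]] / 2.0
        a_m = gt_rng.random(n_snps) < dosages[:, col[m]] / 2.0
        dosages[:, col[c]] = a_f.astype(int) + a_m.astype(int)
    return pedigree, GenotypeMatrix(snps, samples, dosages)


def simulate_methylome(pedigree: PedigreeSet, genotypes: GenotypeMatrix,
                       effect: EffectConfig) -> tuple[MethylationMatrix, CohortTruth]:
    """Simulate the methylation matrix given genotypes, and return truth.

    Per sample and CpG the latent methylation is
    ``baseline + cis_beta * dosage + family-shared noise + residual noise``
    clamped to [0, 1]; at SNP-CpG destruction sites the observed latent is
    scaled by (2 - dosage)/2; observed fractions are Binomial(depth,
    latent)/depth with per-cell Poisson depth (or exactly latent in
    infinite-depth mode).
    """
    cpg_sites, snps = _layout(effect)
    if list(snps["id"]) != list(genotypes.snps["id"]):
        raise ValueError("genotype matrix does not match this EffectConfig layout")
    samples = genotypes.samples
    missing_ped = set(samples) - set(pedigree.sample_ids)
    if missing_ped:
        raise ValueError(f"genotype samples not in pedigree: {sorted(missing_ped)}")
    n_cpgs, n_samples = effect.n_cpgs, len(samples)
    rng = _rng(effect.seed, "methylome")
    row_of = {sid: i for i, sid in enumerate(snps["id"])}

    baseline = rng.beta(*effect.baseline_beta, size=n_cpgs)
    latent = np.repeat(baseline[:, None], n_samples, axis=1)

    for snp, cpg, beta in effect.cis_effects:
        latent[cpg] += beta * np.nan_to_num(genotypes.dosages[row_of[f"snp{snp}"]])

    fam_of = pedigree.family_of()
    fam_ids = sorted({fam_of[s] for s in samples})
    fam_idx = {f: k for k, f in enumerate(fam_ids)}
    sample_fam = np.array([fam_idx[fam_of[s]] for s in samples])
    if effect.family_noise_cpgs:
        fam_noise = rng.normal(0.0, effect.family_noise_sd,
                               size=(len(effect.family_noise_cpgs), len(fam_ids)))
        for k, cpg in enumerate(effect.family_noise_cpgs):
            latent[cpg] += fam_noise[k, sample_fam]

    sd = np.full((n_cpgs, n_samples), effect.residual_sd)
    for snp, cpgs, s0, s1, s2 in effect.vsnp_effects:
        d = genotypes.dosages[row_of[f"snp{snp}"]]
        sig = np.where(np.isnan(d), effect.residual_sd,
                       np.choose(np.nan_to_num(d).astype(int), [s0, s1, s2]))
        for cpg in cpgs:
            sd[cpg] = sig
    latent += rng.normal(0.0, 1.0, size=(n_cpgs, n_samples)) * sd
    latent = np.clip(latent, 0.0, 1.0)

    for snp, cpg in effect.snp_cpg_sites:
        d = genotypes.dosages[row_of[f"snp{snp}"]]
        latent[cpg] *= (2.0 - d) / 2.0  # NaN dosage propagates to missing

    if effect.read_depth is None:
        observed = latent.copy()
        depths = np.full(latent.shape, 1_000_000, dtype=int)
    else:
        depths = rng.poisson(effect.read_depth, size=latent.shape)
        with np.errstate(invalid="ignore"):
            counts = rng.binomial(depths, np.nan_to_num(latent))
        observed = np.where(depths > 0, counts / np.maximum(depths, 1), np.nan)
    observed = np.where(np.isnan(latent), np.nan, observed)

    classes = np.array(["null"] * n_cpgs, dtype=object)
    for cpg in effect.family_noise_cpgs:
        classes[cpg] = "family"
    for _, cpg, _b in effect.cis_effects:
        classes[cpg] = "cis"
    for _, cpgs, *_ in effect.vsnp_effects:
        for cpg in cpgs:
            classes[cpg] = "vsnp"
    for _, cpg in effect.snp_cpg_sites:
        classes[cpg] = "snp_cpg"

    pos = cpg_sites["pos"].to_numpy()
    allele_probs = {}
    for snp, cpg, beta in effect.cis_effects:
        p_ref = float(np.clip(baseline[cpg], 0, 1))
        p_alt = float(np.clip(baseline[cpg] + 2.0 * beta, 0, 1))
        allele_probs[(f"snp{snp}", int(pos[cpg]))] = (p_ref, p_alt)
    for snp, cpg in effect.snp_cpg_sites:
        p_ref = float(np.clip(baseline[cpg], 0, 1))
        allele_probs[(f"snp{snp}", int(pos[cpg]))] = (p_ref, 0.0)

    truth = CohortTruth(
        cpg_class=pd.DataFrame({"chrom": cpg_sites["chrom"],
                                "pos": cpg_sites["pos"], "class": classes}),
        snp_cpg_pairs=[(f"snp{s}", int(pos[c])) for s, c in effect.snp_cpg_sites],
        cis_pairs=[(f"snp{s}", int(pos[c]), b) for s, c, b in effect.cis_effects],
        vsnp_blocks=[{"snp_id": f"snp{s}",
                      "cpg_positions": [int(pos[c]) for c in cpgs],
                      "sigmas": (s0, s1, s2)}
                     for s, cpgs, s0, s1, s2 in effect.vsnp_effects],
        family_noise_positions=[int(pos[c]) for c in effect.family_noise_cpgs],
        baseline=baseline,
        allele_meth_probs=allele_probs,
    )
    meth = MethylationMatrix(cpg_sites, list(samples), observed, depths)
    return meth, truth


def simulate_allelic_fragments(genotypes: GenotypeMatrix, truth: CohortTruth,
                               depth: int, seed: int) -> AllelicFragmentSet:
    """Simulate allele-tagged read fragments at heterozygous effect SNPs.

    For every (SNP, CpG) pair carrying allele-specific methylation
    probabilities in the truth, each sample heterozygous at the SNP
    contributes ``depth`` fragments; the fragment's allele is drawn fairly
    and its methylation state is Bernoulli with the allele's probability.
    """
    if depth < 0:
        raise ValueError("depth must be >= 0")
    rng = _rng(seed, "fragments")
    row_of = {sid: i for i, sid in enumerate(genotypes.snps["id"])}
    chrom_of = dict(zip(genotypes.snps["id"], genotypes.snps["chrom"]))
    rows = []
    for (snp_id, cpg_pos), (p_ref, p_alt) in sorted(truth.allele_meth_probs.items()):
        d = genotypes.dosages[row_of[snp_id]]
        for j, sample in enumerate(genotypes.samples):
            if d[j] != 1:  # fragments only at heterozygous (sample, SNP)
                continue
            alleles = rng.integers(0, 2, size=depth)  # 0=ref, 1=alt
            p = np.where(alleles == 1, p_alt, p_ref)
            meth = rng.random(depth) < p
            for a, m in zip(alleles, meth):
                rows.append((sample, snp_id, chrom_of[snp_id], cpg_pos,
                             "alt" if a else "ref", bool(m)))
    records = pd.DataFrame(rows, columns=AllelicFragmentSet.REQUIRED)
    return AllelicFragmentSet(records)
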