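"""Analysis configuration: every numeric threshold of the study in one place.

Defaults are the published study's values; see docs/methods.md for what each
controls and where it enters the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import hashlib
import json


@dataclass
class AnalysisConfig:
    """All tunable thresholds of the pipeline.

    Attributes
    ----------
    min_depth : int
        Minimum read depth for a methylation measurement to be trusted.
    min_present_fraction : float
        Minimum fraction of samples with a valid measurement for a CpG site
        to be retained (inclusive).
    sd_variable : float
        Minimum across-sample SD for a CpG to count as "variable" (inclusive).
    sd_highly_variable : float
        SD threshold for the "highly variable" CpG subset.
    h2_min : float
        Mid-parent-offspring slope a CpG must exceed (strict) to be heritable.
    min_trios : int
        Minimum number of complete trios contributing to the MPO regression.
    fdr : float
        Benjamini-Hochberg FDR cutoff used for heritable-CpG and mQTL calls.
    window : int
        cis window in bp: CpG-SNP pairs tested when |SNP - CpG| <= window.
    maf_min : float
        Minimum minor allele frequency for a SNP to enter analysis (inclusive).
    hwe_min_p : float
        Hardy-Weinberg exact-test p-value a SNP must exceed (strict).
    n_perm : int
        Number of family-aware permutations for empirical mQTL p-values.
    asm_p_max : float
        Fisher exact p-value an ASM event must fall below (strict).
    asm_delta_min : float
        Minimum absolute between-allele methylation difference (strict).
    asm_min_per_allele : int
        Minimum fragment count on each allele for an ASM table to be testable.
    vmr_min_cpgs : int
        Minimum number of adjacent consistently-associated CpGs in a VMR.
    vmr_max_spacing : int
        Maximum bp between consecutive CpGs within one VMR.
    vmr_cluster_distance : int
        Edge-to-edge bp distance within which VMRs merge into one cluster.
    vmr_min_group_n : int
        Minimum samples per genotype class for a variance regression.
    vmr_fpr_target : float
        Permutation false-positive-rate target used when calibrating the
        variance-regression t cutoff.
    vmr_t_min : float or None
        Direct t cutoff for VMR membership; None means calibrate by
        permutation to ``vmr_fpr_target``.
    include_sex_chromosomes : bool
        Whether sex-chromosome CpGs are kept (analysis is autosomal by default).
    seed : int
        Base seed; per-stage streams are derived from it.
    """

    min_depth: int = 10
    min_present_fraction: float = 0.8
    sd_variable: float = 0.1
    sd_highly_variable: float = 0.3
    h2_min: float = 0.2
    min_trios: int = 10
    fdr: float = 0.05
    window: int = 1_000_000
    maf_min: float = 0.05
    hwe_min_p: float = 0.001
    n_perm: int = 10_000
    asm_p_max: float = 0.001
    asm_delta_min: float = 0.2
    asm_min_per_allele: int = 5
    vmr_min_cpgs: int = 5
    vmr_max_spacing: int = 200
    vmr_cluster_distance: int = 100_000
    vmr_min_group_n: int = 3
    vmr_fpr_target: float = 0.10
    vmr_t_min: float | None = None
    include_sex_chromosomes: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("min_present_fraction", "sd_variable", "sd_highly_variable",
                     "fdr", "maf_min", "hwe_min_p", "asm_p_max", "asm_delta_min",
                     "vmr_fpr_target"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("min_depth", "window", "n_perm", "vmr_max_spacing",
                     "vmr_cluster_distance"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("min_trios", "vmr_min_cpgs", "vmr_min_group_n"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")

    def to_dict(self) -> dict:
        return asdict(self)

    def hash(self) -> str:
        """Stable hash of the configuration, stamped on every output."""
        blob = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)
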