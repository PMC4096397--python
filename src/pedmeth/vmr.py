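"""Variance-QTL (vSNP) and variably methylated region (VMR) detection.

A vSNP modulates the *variance* of methylation at nearby CpGs rather than
the mean. For each cis (CpG, SNP) pair, methylation variance is computed
within each genotype class (AA, AB, BB) and regressed on the genotype code
(0, 1, 2); the slope's t-score (1 residual degree of freedom) measures the
variance trend. Because each regression has only three points, single-pair
calls are noisy; a VMR therefore requires a run of at least ``min_cpgs``
adjacent CpGs (spacing <= ``max_spacing``) whose scores agree in sign and
exceed the t cutoff for the same SNP. The false-positive rate of the whole
procedure is estimated by re-running it on methylation matrices with
permuted sample labels, and the t cutoff can be calibrated to hit a target
permutation FPR. Overlapping or nearby VMRs (possibly driven by different
vSNPs) are grouped into clusters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, MethylationMatrix

log = logging.getLogger(__name__)

T_GRID_DEFAULT = (1.5, 2.0, 2.5, 3.0, 3.5, 4.0, 5.0, 6.0, 8.0, 12.0)


def variance_regression(y: np.ndarray, dosage: np.ndarray,
                        min_group_n: int = 3):
    """Regress per-genotype methylation variance on genotype code.

    ``y`` and ``dosage`` are per-sample vectors (NaN = missing). Sample
    variances are computed within each genotype class over non-missing
    values; OLS of the three variances on codes (0, 1, 2) yields the slope
    and its t-score with 1 residual df. Returns None (untestable) when any
    class has fewer than ``min_group_n`` samples or fewer than 3 classes
    are present.
    """
    variances = []
    for code in (0, 1, 2):
        vals = y[(dosage == code) & ~np.isnan(y)]
        if len(vals) < min_group_n or len(vals) < 2:
            return None
        variances.append(float(np.var(vals, ddof=1)))
    return _three_point_slope_t(np.array(variances))


def _three_point_slope_t(v: np.ndarray):
    """OLS slope and t for three points on x = (0, 1, 2)."""
    x = np.array([0.0, 1.0, 2.0])
    slope = float(np.sum((x - 1.0) * v) / 2.0)
    fitted = v.mean() + slope * (x - 1.0)
    sse = float(np.sum((v - fitted) ** 2))
    sxx = 2.0
    if sse <= 0:
        t = np.inf if slope > 0 else (-np.inf if slope < 0 else 0.0)
    else:
        se = np.sqrt(sse / 1.0 / sxx)
        t = slope / se
    return slope, float(t)


def variance_scan(m: MethylationMatrix, g: GenotypeMatrix,
                  window: int = 1_000_000,
                  min_group_n: int = 3) -> pd.DataFrame:
    """Variance regression for every cis (CpG, SNP) pair within ``window``."""
    shared = [s for s in m.samples if s in set(g.samples)]
    if not shared:
        raise ValueError("no samples shared between methylation and genotypes")
    mm = m.subset_samples(shared) if shared != list(m.samples) else m
    gg = g.subset_samples(shared) if shared != list(g.samples) else g

    rows = []
    for chrom, snp_grp in gg.snps.groupby("chrom", sort=False):
        site_idx = np.flatnonzero((mm.sites["chrom"] == chrom).to_numpy())
        if len(site_idx) == 0:
            continue
        cpg_pos = mm.sites["pos"].to_numpy()[site_idx]
        snp_pos = snp_grp["pos"].to_numpy()
        snp_rows = snp_grp.index.to_numpy()
        lo = np.searchsorted(snp_pos, cpg_pos - window, side="left")
        hi = np.searchsorted(snp_pos, cpg_pos + window, side="right")
        for k, ci in enumerate(site_idx):
            y = mm.values[ci]
            for j in range(lo[k], hi[k]):
                si = snp_rows[j]
                res = variance_regression(y, gg.dosages[si], min_group_n)
                if res is None:
                    continue
                slope, t = res
                rows.append((chrom, int(cpg_pos[k]), gg.snps.at[si, "id"],
                             int(snp_pos[j]), slope, t))
    return pd.DataFrame(rows, columns=["chrom", "cpg_pos", "snp_id",
                                       "snp_pos", "slope", "t"])


def call_vmrs(scores: pd.DataFrame, t_min: float, min_cpgs: int = 5,
              max_spacing: int = 200) -> pd.DataFrame:
    """Call VMRs from per-pair variance scores.

    For each SNP, CpGs are scanned in genomic order; maximal runs of
    consecutive CpGs with |t| >= t_min, a shared slope sign, and inter-CpG
    spacing <= max_spacing are emitted as VMRs when they contain at least
    ``min_cpgs`` members. "Adjacent" means consecutive among the analyzed
    CpGs. Returns one row per VMR.
    """
    vmrs = []
    if len(scores) == 0:
        return _vmr_frame(vmrs)
    for (snp, chrom), grp in scores.groupby(["snp_id", "chrom"], sort=True):
        grp = grp.sort_values("cpg_pos")
        pos = grp["cpg_pos"].to_numpy()
        t = grp["t"].to_numpy()
        sign = np.sign(grp["slope"].to_numpy())
        qual = np.abs(t) >= t_min
        run: list[int] = []
        for i in range(len(grp)):
            extends = (qual[i] and run
                       and sign[i] == sign[run[-1]] and sign[i] != 0
                       and pos[i] - pos[run[-1]] <= max_spacing)
            if extends:
                run.append(i)
            else:
                if len(run) >= min_cpgs:
                    vmrs.append(_make_vmr(snp, chrom, grp, run))
                run = [i] if (qual[i] and sign[i] != 0) else []
        if len(run) >= min_cpgs:
            vmrs.append(_make_vmr(snp, chrom, grp, run))
    return _vmr_frame(vmrs)


def _make_vmr(snp, chrom, grp, run) -> dict:
    pos = grp["cpg_pos"].to_numpy()[run]
    t = grp["t"].to_numpy()[run]
    return {"snp_id": snp, "chrom": chrom,
            "start": int(pos.min()), "end": int(pos.max()),
            "n_cpgs": len(run),
            "cpg_positions": ",".join(str(int(p)) for p in pos),
            "direction": int(np.sign(t[0])),
            "t_scores": ",".join(f"{x:.3f}" for x in t)}


def _vmr_frame(vmrs: list[dict]) -> pd.DataFrame:
    return pd.DataFrame(vmrs, columns=["snp_id", "chrom", "start", "end",
                                       "n_cpgs", "cpg_positions", "direction",
                                       "t_scores"])


def permute_sample_labels(m: MethylationMatrix,
                          rng: np.random.Generator) -> MethylationMatrix:
    """Shuffle sample columns, breaking the genotype linkage while
    preserving each CpG's marginal distribution."""
    perm = rng.permutation(m.n_samples)
    return MethylationMatrix(m.sites.copy(), list(m.samples),
                             m.values[:, perm], m.depths[:, perm])


@dataclass
class FprEstimate:
    observed_calls: int
    mean_permuted_calls: float
    fpr: float  # NaN when observed_calls == 0
    per_permutation_calls: list[int]


def estimate_fpr_by_permutation(m: MethylationMatrix, g: GenotypeMatrix,
                                t_min: float, min_cpgs: int = 5,
                                max_spacing: int = 200,
                                window: int = 1_000_000, min_group_n: int = 3,
                                n_perm: int = 10, seed: int = 0) -> FprEstimate:
    """Estimate the VMR false-positive rate by label permutation.

    The full scan + call procedure is re-run on ``n_perm`` matrices with
    permuted sample labels; the FPR estimate is mean permuted call count /
    observed call count (NaN when nothing was observed). Deterministic
    given the seed.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    observed = len(call_vmrs(variance_scan(m, g, window, min_group_n),
                             t_min, min_cpgs, max_spacing))
    rng = np.random.default_rng(seed)
    counts = []
    for _ in range(n_perm):
        mp = permute_sample_labels(m, rng)
        counts.append(len(call_vmrs(variance_scan(mp, g, window, min_group_n),
                                    t_min, min_cpgs, max_spacing)))
    mean_perm = float(np.mean(counts))
    fpr = mean_perm / observed if observed > 0 else np.nan
    if observed == 0:
        log.warning("estimate_fpr_by_permutation: no observed VMRs; "
                    "reporting counts only")
    return FprEstimate(observed, mean_perm, fpr, counts)


def choose_t_min_by_fpr(m: MethylationMatrix, g: GenotypeMatrix,
                        fpr_target: float = 0.10,
                        grid: tuple[float, ...] = T_GRID_DEFAULT,
                        min_cpgs: int = 5, max_spacing: int = 200,
                        window: int = 1_000_000, min_group_n: int = 3,
                        n_perm: int = 10, seed: int = 0) -> float:
    """Smallest grid cutoff whose permutation-estimated FPR is <= target.

    Scans a grid of t cutoffs from permissive to strict (the cutoff grid
    plays the role of a false-discovery sweep over test-statistic values)
    and returns the first cutoff whose estimated FPR meets the target.
    When no cutoff meets the target, the cutoff with the smallest estimated
    FPR among those still producing calls is returned (ties broken toward
    the stricter cutoff) — a cutoff that calls nothing would control FPR
    only vacuously. When nothing is called at any cutoff, the most
    permissive grid value is returned.
    """
    scores = variance_scan(m, g, window, min_group_n)
    rng = np.random.default_rng(seed)
    perms = [permute_sample_labels(m, rng) for _ in range(n_perm)]
    perm_scores = [variance_scan(mp, g, window, min_group_n) for mp in perms]
    fprs: list[tuple[float, float]] = []  # (fpr, t_min) where obs > 0
    for t_min in sorted(grid):
        obs = len(call_vmrs(scores, t_min, min_cpgs, max_spacing))
        if obs == 0:
            continue
        mean_perm = float(np.mean(
            [len(call_vmrs(ps, t_min, min_cpgs, max_spacing))
             for ps in perm_scores]))
        if mean_perm / obs <= fpr_target:
            return float(t_min)
        fprs.append((mean_perm / obs, float(t_min)))
    if fprs:
        best = min(f for f, _ in fprs)
        return max(t for f, t in fprs if f == best)
    return float(min(grid))


def cluster_vmrs(vmrs: pd.DataFrame, max_distance: int = 100_000) -> pd.DataFrame:
    """Single-linkage grouping of VMRs within ``max_distance`` bp
    (edge-to-edge, inclusive); overlapping VMRs from different vSNPs merge.
    Order-independent and idempotent."""
    if len(vmrs) == 0:
        return pd.DataFrame(columns=["cluster_id", "chrom", "start", "end",
                                     "n_vmrs", "snp_ids"])
    rows = []
    cid = 0
    for chrom, grp in vmrs.groupby("chrom", sort=True):
        grp = grp.sort_values(["start", "end"], kind="stable")
        cur: list[pd.Series] = []
        cur_end = None
        for _, row in grp.iterrows():
            if cur and row["start"] - cur_end <= max_distance:
                cur.append(row)
                cur_end = max(cur_end, row["end"])
            else:
                if cur:
                    rows.append(_make_cluster(cid, chrom, cur))
                    cid += 1
                cur = [row]
                cur_end = row["end"]
        if cur:
            rows.append(_make_cluster(cid, chrom, cur))
            cid += 1
    return pd.DataFrame(rows)


def _make_cluster(cid: int, chrom, members: list[pd.Series]) -> dict:
    return {"cluster_id": f"vmrclust{cid}", "chrom": chrom,
            "start": int(min(r["start"] for r in members)),
            "end": int(max(r["end"] for r in members)),
            "n_vmrs": len(members),
            "snp_ids": ",".join(sorted({r["snp_id"] for r in members}))}
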