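"""Site-level QC and variable-CpG selection for methylation matrices.

The standard targeted-bisulfite QC ladder: mask low-depth cells, drop sites
measured in too few samples, restrict to autosomes, and keep only sites
whose across-sample SD marks them as variable. All thresholds are inclusive
(>=) and every filter is idempotent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import MethylationMatrix, is_autosome
from .config import AnalysisConfig

log = logging.getLogger(__name__)


def apply_depth_filter(m: MethylationMatrix, min_depth: int) -> MethylationMatrix:
    """Mask cells with read depth below ``min_depth``; dimensions unchanged."""
    if min_depth < 0:
        raise ValueError("min_depth must be >= 0")
    values = np.where(m.depths >= min_depth, m.values, np.nan)
    return MethylationMatrix(m.sites.copy(), list(m.samples), values,
                             m.depths.copy())


def filter_missingness(m: MethylationMatrix,
                       min_present_fraction: float) -> MethylationMatrix:
    """Drop sites with a valid measurement in fewer than the required
    fraction of samples (inclusive at the threshold)."""
    if not 0.0 <= min_present_fraction <= 1.0:
        raise ValueError("min_present_fraction must be in [0, 1]")
    if m.n_sites == 0:
        return m
    present = (~np.isnan(m.values)).mean(axis=1) if m.n_samples else \
        np.zeros(m.n_sites)
    return m.subset_sites(present >= min_present_fraction)


def site_sd(m: MethylationMatrix) -> np.ndarray:
    """Across-sample SD per site (n-1 denominator, non-missing values only);
    NaN where fewer than 2 values are present."""
    with np.errstate(invalid="ignore", divide="ignore"):
        sd = np.full(m.n_sites, np.nan)
        n = (~np.isnan(m.values)).sum(axis=1)
        ok = n >= 2
        if ok.any():
            sd[ok] = np.nanstd(m.values[ok], axis=1, ddof=1)
    return sd


def select_variable_cpgs(m: MethylationMatrix, sd_min: float) -> MethylationMatrix:
    """Keep sites whose sample SD is >= ``sd_min``; sites with fewer than two
    non-missing values are removed (SD undefined)."""
    sd = site_sd(m)
    keep = ~np.isnan(sd) & (sd >= sd_min)
    return m.subset_sites(keep)


def drop_sex_chromosomes(m: MethylationMatrix) -> MethylationMatrix:
    keep = m.sites["chrom"].map(is_autosome).to_numpy()
    return m.subset_sites(keep)


@dataclass
class StrandConcordance:
    n_shared_sites: int
    per_sample_correlation: pd.Series
    global_correlation: float
    mean_abs_difference: float


def strand_concordance(m_fwd: MethylationMatrix,
                       m_rev: MethylationMatrix) -> StrandConcordance:
    """Agreement between the two strands of the same CG dinucleotides —
    an internal technical replicate. Reports correlations and mean |delta|;
    applies no filtering."""
    if list(m_fwd.samples) != list(m_rev.samples):
        raise ValueError("strand matrices must share sample ordering")
    key_f = m_fwd.site_keys()
    key_r = m_rev.site_keys()
    shared = key_f.intersection(key_r)
    if len(shared) == 0:
        log.warning("strand_concordance: no shared sites")
        return StrandConcordance(0, pd.Series(dtype=float), np.nan, np.nan)
    a = m_fwd.values[key_f.get_indexer(shared)]
    b = m_rev.values[key_r.get_indexer(shared)]
    diff = np.abs(a - b)
    mean_abs = float(np.nanmean(diff)) if np.isfinite(diff).any() else np.nan

    def _corr(x, y):
        ok = ~np.isnan(x) & ~np.isnan(y)
        if ok.sum() < 2 or np.nanstd(x[ok]) == 0 or np.nanstd(y[ok]) == 0:
            return np.nan
        return float(np.corrcoef(x[ok], y[ok])[0, 1])

    per_sample = pd.Series({s: _corr(a[:, j], b[:, j])
                            for j, s in enumerate(m_fwd.samples)})
    global_corr = _corr(a.ravel(), b.ravel())
    return StrandConcordance(len(shared), per_sample, global_corr, mean_abs)


def qc_pipeline(m: MethylationMatrix, config: AnalysisConfig
                ) -> tuple[MethylationMatrix, pd.DataFrame]:
    """Depth mask -> missingness filter -> autosome restriction -> variable
    CpG selection, returning the filtered matrix and a per-step QC report."""
    steps = []
    steps.append(("input", m.n_sites))
    m = apply_depth_filter(m, config.min_depth)
    m = filter_missingness(m, config.min_present_fraction)
    steps.append(("depth+missingness", m.n_sites))
    if not config.include_sex_chromosomes:
        m = drop_sex_chromosomes(m)
        steps.append(("autosomal", m.n_sites))
    m = select_variable_cpgs(m, config.sd_variable)
    steps.append((f"variable (SD>={config.sd_variable})", m.n_sites))
    report = pd.DataFrame(steps, columns=["step", "n_sites"])
    for step, n in steps:
        log.info("qc: %s -> %d sites", step, n)
    return m, report
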