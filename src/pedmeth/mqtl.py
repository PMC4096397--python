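"""cis-mQTL mapping: SNP QC and per-pair least-squares association with
family-aware permutation p-values.

Each (CpG, SNP) pair within the cis window is tested by OLS of methylation
on additive alt-allele dosage. Asymptotic p-values come from the slope
t-test; empirical p-values from permutations that shuffle whole-family
phenotype blocks among families of identical size and then member labels
within each family, preserving familial correlation under the null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import lgamma

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import GenotypeMatrix, MethylationMatrix, PedigreeSet, TrioSet

log = logging.getLogger(__name__)


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (q-values), input order preserved."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.array([])
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def hwe_test(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact Hardy-Weinberg test p-value from genotype counts.

    Conditional on the observed allele counts, sums the probabilities of
    all heterozygote counts whose probability does not exceed the observed
    configuration's. Monomorphic SNPs return p = 1.
    """
    if min(n_aa, n_ab, n_bb) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_aa + n_ab + n_bb
    if n < 1:
        raise ValueError("at least one genotype required")
    n_alt = 2 * n_bb + n_ab  # alt allele count
    if n_alt == 0 or n_alt == 2 * n:
        return 1.0

    def log_prob(h: int) -> float:
        # Levene-Haldane: P(het=h | n, n_alt) = n! n_alt! n_ref! 2^h / (a! h! r! (2n)!)
        a = (n_alt - h) // 2   # hom alt
        r = n - h - a          # hom ref
        return (lgamma(n + 1) - lgamma(r + 1) - lgamma(h + 1) - lgamma(a + 1)
                + h * np.log(2)
                + lgamma(n_alt + 1) + lgamma(2 * n - n_alt + 1) - lgamma(2 * n + 1))

    # valid het counts share the parity of n_alt and satisfy the margins
    h_min = n_alt % 2
    h_max = min(n_alt, 2 * n - n_alt)
    hs = np.arange(h_min, h_max + 1, 2)
    logp = np.array([log_prob(int(h)) for h in hs])
    logp -= _logsumexp(logp)
    probs = np.exp(logp)
    obs = probs[np.searchsorted(hs, n_ab)]
    return float(min(probs[probs <= obs * (1 + 1e-12)].sum(), 1.0))


def _logsumexp(x: np.ndarray) -> float:
    m = x.max()
    return float(m + np.log(np.exp(x - m).sum()))


def mendel_errors(g: GenotypeMatrix, trios: TrioSet,
                  family_of: dict[str, str] | None = None) -> pd.DataFrame:
    """Count Mendelian-impossible trio genotype combinations per SNP x trio.

    A combination is impossible when the child's dosage cannot arise from
    one transmitted allele per parent (e.g. 0 x 0 parents with a het child).
    Returns one row per trio with its error count over all SNPs, plus the
    number of fully genotyped (SNP, trio) tests.
    """
    col = {s: j for j, s in enumerate(g.samples)}
    transmissible = {0: {0}, 1: {0, 1}, 2: {1}}
    rows = []
    for f, m, c in trios:
        if f not in col or m not in col or c not in col:
            continue
        df, dm, dc = (g.dosages[:, col[s]] for s in (f, m, c))
        ok = ~(np.isnan(df) | np.isnan(dm) | np.isnan(dc))
        errs = 0
        for i in np.flatnonzero(ok):
            possible = {af + am
                        for af in transmissible[int(df[i])]
                        for am in transmissible[int(dm[i])]}
            if int(dc[i]) not in possible:
                errs += 1
        rows.append({
            "family_id": family_of.get(c) if family_of else None,
            "father_id": f, "mother_id": m, "child_id": c,
            "n_errors": errs, "n_tested": int(ok.sum()),
        })
    return pd.DataFrame(rows, columns=["family_id", "father_id", "mother_id",
                                       "child_id", "n_errors", "n_tested"])


def snp_qc(g: GenotypeMatrix, trios: TrioSet, maf_min: float = 0.05,
           hwe_min_p: float = 0.001,
           family_of: dict[str, str] | None = None,
           founders: list[str] | None = None
           ) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """MAF and exact-HWE SNP filters plus a Mendel-error report.

    MAF is computed from all non-missing samples pooled; SNPs are kept iff
    MAF >= maf_min and HWE p > hwe_min_p (strict). HWE counts come from
    founders when given (children duplicate parental alleles), else all
    samples.
    """
    d = g.dosages
    alt = np.nansum(d, axis=1)
    n_obs = (~np.isnan(d)).sum(axis=1)
    with np.errstate(invalid="ignore"):
        f_alt = np.where(n_obs > 0, alt / (2 * n_obs), np.nan)
    maf = np.minimum(f_alt, 1 - f_alt)

    if founders:
        cols = [g.samples.index(s) for s in founders if s in g.samples]
        dh = d[:, cols]
    else:
        dh = d
    hwe_p = np.ones(g.n_snps)
    for i in range(g.n_snps):
        row = dh[i]
        row = row[~np.isnan(row)]
        if row.size == 0:
            hwe_p[i] = 1.0
            continue
        n_bb = int((row == 2).sum())
        n_ab = int((row == 1).sum())
        n_aa = int((row == 0).sum())
        hwe_p[i] = hwe_test(n_aa, n_ab, n_bb)

    keep = (maf >= maf_min) & (hwe_p > hwe_min_p) & (n_obs > 0)
    filtered = g.subset_snps(keep)
    if filtered.n_snps == 0:
        log.warning("snp_qc: all %d SNPs filtered out", g.n_snps)
    report = mendel_errors(g, trios, family_of=family_of)
    return filtered, report


def family_permutations(samples: list[str], pedigree: PedigreeSet | None,
                        n_perm: int, rng: np.random.Generator) -> np.ndarray:
    """Permutation index matrix preserving family block structure.

    Whole-family phenotype blocks are permuted among families of identical
    size, then member labels are shuffled within each family. Samples
    without pedigree information form singleton blocks. Returns an
    (n_perm, n_samples) integer array P with y_perm = y[P[k]].
    """
    fam_of = pedigree.family_of() if pedigree is not None else {}
    members: dict[str, list[int]] = {}
    for j, s in enumerate(samples):
        members.setdefault(fam_of.get(s, f"__solo_{s}"), []).append(j)
    by_size: dict[int, list[list[int]]] = {}
    for mem in members.values():
        by_size.setdefault(len(mem), []).append(mem)

    n = len(samples)
    P = np.empty((n_perm, n), dtype=int)
    for k in range(n_perm):
        idx = np.empty(n, dtype=int)
        for size, fams in by_size.items():
            order = rng.permutation(len(fams))
            for slot, donor in zip(fams, (fams[o] for o in order)):
                shuffled = rng.permutation(donor)
                idx[np.asarray(slot)] = shuffled
        P[k] = idx
    return P


def _pair_stats(x: np.ndarray, y: np.ndarray):
    """Complete-case OLS slope, t and two-sided p for one pair."""
    ok = ~np.isnan(x) & ~np.isnan(y)
    n = int(ok.sum())
    if n < 3:
        return None
    xs, ys = x[ok], y[ok]
    sxx = np.sum((xs - xs.mean()) ** 2)
    if sxx == 0:
        return None
    sxy = np.sum((xs - xs.mean()) * (ys - ys.mean()))
    syy = np.sum((ys - ys.mean()) ** 2)
    beta = sxy / sxx
    sse = max(syy - beta * sxy, 0.0)
    if n == 3 and sse == 0:
        t = np.inf if beta != 0 else 0.0
    else:
        s2 = sse / (n - 2)
        t = beta / np.sqrt(s2 / sxx) if s2 > 0 else \
            (np.inf if beta > 0 else (-np.inf if beta < 0 else 0.0))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2) if np.isfinite(t) else 0.0
    if t == 0.0:
        p = 1.0
    return beta, float(t), float(p), n, ok


def _perm_abs_t(x: np.ndarray, Yp: np.ndarray) -> np.ndarray:
    """|t| of the OLS slope for each permuted phenotype row (NaN-aware)."""
    w = ~np.isnan(Yp) & ~np.isnan(x)
    xf = np.nan_to_num(x)
    yf = np.nan_to_num(Yp)
    n = w.sum(axis=1)
    sx = w @ xf
    sxx = w @ (xf * xf)
    sy = (yf * w).sum(axis=1)
    syy = (yf * yf * w).sum(axis=1)
    sxy = (yf * (w * xf)).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxy - sx * sy / n
        varx = sxx - sx * sx / n
        vary = syy - sy * sy / n
        denom = varx * vary - cov * cov
        t2 = np.where(denom > 0, cov * cov * (n - 2) / denom, np.inf)
        t2 = np.where((varx <= 0) | (vary <= 0) | (n < 3), np.nan, t2)
    return np.sqrt(t2)


def mqtl_scan(m: MethylationMatrix, g: GenotypeMatrix,
              pedigree: PedigreeSet | None = None,
              window: int = 1_000_000, n_perm: int = 10_000,
              seed: int = 0, smooth_empirical_p: bool = False) -> pd.DataFrame:
    """Scan all cis (CpG, SNP) pairs: |SNP pos - CpG pos| <= window.

    Returns one row per tested pair with the OLS slope (beta), t statistic,
    asymptotic p, empirical permutation p (fraction of permutations with
    |t_perm| > |t_obs|; NaN when n_perm = 0) and BH q over all tested pairs
    (on the empirical p when permutations were run, else the asymptotic p).
    Pairs with fewer than 3 complete observations or no genotype variance
    are skipped. Deterministic given the seed.
    """
    shared = [s for s in m.samples if s in set(g.samples)]
    if not shared:
        raise ValueError("no samples shared between methylation and genotypes")
    mm = m.subset_samples(shared) if shared != list(m.samples) else m
    gg = g.subset_samples(shared) if shared != list(g.samples) else g

    rng = np.random.default_rng(seed)
    P = family_permutations(shared, pedigree, n_perm, rng) if n_perm > 0 else None

    rows = []
    for chrom, snp_grp in gg.snps.groupby("chrom", sort=False):
        site_mask = (mm.sites["chrom"] == chrom).to_numpy()
        site_idx = np.flatnonzero(site_mask)
        if len(site_idx) == 0:
            continue
        cpg_pos = mm.sites["pos"].to_numpy()[site_idx]
        snp_pos = snp_grp["pos"].to_numpy()
        snp_rows = snp_grp.index.to_numpy()
        lo = np.searchsorted(snp_pos, cpg_pos - window, side="left")
        hi = np.searchsorted(snp_pos, cpg_pos + window, side="right")
        for k, ci in enumerate(site_idx):
            if lo[k] >= hi[k]:
                continue
            y = mm.values[ci]
            Yp = y[P] if P is not None else None
            for j in range(lo[k], hi[k]):
                si = snp_rows[j]
                x = gg.dosages[si]
                st = _pair_stats(x, y)
                if st is None:
                    continue
                beta, t, p_asym, n, _ok = st
                p_emp = np.nan
                if P is not None:
                    abs_t = _perm_abs_t(x, Yp)
                    k_exceed = int(np.nansum(abs_t > abs(t)))
                    if smooth_empirical_p:
                        p_emp = (k_exceed + 1) / (n_perm + 1)
                    else:
                        p_emp = k_exceed / n_perm
                rows.append((mm.sites.at[ci, "chrom"],
                             int(mm.sites.at[ci, "pos"]),
                             gg.snps.at[si, "id"],
                             int(snp_pos[j]) - int(cpg_pos[k]),
                             beta, t, p_asym, p_emp, n))

    out = pd.DataFrame(rows, columns=["chrom", "cpg_pos", "snp_id", "distance",
                                      "beta", "t", "p_asym", "p_emp", "n"])
    p_for_fdr = out["p_emp"] if (n_perm > 0 and len(out)) else out["p_asym"]
    out["q"] = bh_fdr(p_for_fdr.to_numpy()) if len(out) else np.nan
    return out
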