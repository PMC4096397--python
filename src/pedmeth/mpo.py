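"""Mid-parent-offspring (MPO) heritability of CpG methylation.

For each CpG, the child's methylation is regressed on the mean of its two
parents' methylation across all complete trios; the OLS slope estimates the
narrow-sense heritability h2. Heritable CpGs are those exceeding a slope
threshold with enough trios and a BH-adjusted regression p-value under the
FDR cutoff. CpGs whose dinucleotide harbors a polymorphic SNP ("SNP-CpGs")
are flagged separately, and heritable non-SNP CpGs lying close together are
grouped into clusters.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GenotypeMatrix, MethylationMatrix, TrioSet
from .mqtl import bh_fdr

RESULT_COLUMNS = ["chrom", "pos", "h2", "se", "p", "q", "n_trios",
                  "heritable", "snp_cpg"]


def midparent_regression(m: MethylationMatrix, trios: TrioSet) -> pd.DataFrame:
    """Per-CpG OLS of child methylation on mid-parent methylation.

    A trio contributes to a CpG only when father, mother and child all have
    non-missing values there. Returns one row per CpG with the slope (h2),
    its standard error, the two-sided t-test p-value on the slope, and the
    number of contributing trios. CpGs with fewer than 3 trios, or with
    zero variance in the mid-parent values, get NaN p (untestable).
    """
    col = {s: j for j, s in enumerate(m.samples)}
    usable = [(f, m_, c) for f, m_, c in trios
              if f in col and m_ in col and c in col]
    fa = np.array([col[f] for f, _, _ in usable], dtype=int)
    mo = np.array([col[mm] for _, mm, _ in usable], dtype=int)
    ch = np.array([col[c] for _, _, c in usable], dtype=int)

    n_sites = m.n_sites
    h2 = np.full(n_sites, np.nan)
    se = np.full(n_sites, np.nan)
    p = np.full(n_sites, np.nan)
    n_used = np.zeros(n_sites, dtype=int)

    if usable:
        vf, vm, vc = m.values[:, fa], m.values[:, mo], m.values[:, ch]
        mid = (vf + vm) / 2.0
        ok = ~np.isnan(mid) & ~np.isnan(vc)
        n_used = ok.sum(axis=1)
        for i in np.flatnonzero(n_used >= 3):
            x = mid[i, ok[i]]
            y = vc[i, ok[i]]
            n = len(x)
            sxx = np.sum((x - x.mean()) ** 2)
            if sxx == 0:
                continue  # untestable: no spread in mid-parent values
            sxy = np.sum((x - x.mean()) * (y - y.mean()))
            slope = sxy / sxx
            resid = y - (y.mean() + slope * (x - x.mean()))
            sse = float(np.sum(resid ** 2))
            h2[i] = slope
            if n > 2:
                s2 = sse / (n - 2)
                se_i = np.sqrt(s2 / sxx)
                se[i] = se_i
                if se_i > 0:
                    t = slope / se_i
                    p[i] = 2.0 * stats.t.sf(abs(t), df=n - 2)
                else:
                    p[i] = 0.0  # perfect fit with non-zero slope
                    if slope == 0:
                        p[i] = 1.0

    out = pd.DataFrame({
        "chrom": m.sites["chrom"], "pos": m.sites["pos"],
        "h2": h2, "se": se, "p": p, "q": np.nan, "n_trios": n_used,
        "heritable": False, "snp_cpg": False,
    })
    return out


def call_heritable_cpgs(results: pd.DataFrame, h2_min: float = 0.2,
                        min_trios: int = 10, fdr: float = 0.05,
                        fdr_after_h2_filter: bool = False) -> pd.DataFrame:
    """Flag heritable CpGs: h2 > h2_min (strict), n_trios >= min_trios, and
    BH q < fdr.

    BH is computed over all CpGs with a defined p-value by default;
    ``fdr_after_h2_filter=True`` instead adjusts only among the
    h2/trio-qualifying candidates.
    """
    out = results.copy()
    out["q"] = np.nan
    candidates = (out["h2"] > h2_min) & (out["n_trios"] >= min_trios)
    if fdr_after_h2_filter:
        testable = out["p"].notna() & candidates
    else:
        testable = out["p"].notna()
    if testable.any():
        out.loc[testable, "q"] = bh_fdr(out.loc[testable, "p"].to_numpy())
    out["heritable"] = candidates & (out["q"] < fdr)
    return out


def classify_snp_cpg(results: pd.DataFrame,
                     genotypes: GenotypeMatrix) -> pd.DataFrame:
    """Flag CpGs whose dinucleotide itself harbors a polymorphic SNP.

    A CpG is a SNP-CpG when any polymorphic SNP sits exactly on the C
    (position) or the G (position + 1) of the dinucleotide.
    """
    poly = genotypes.polymorphic_positions()
    out = results.copy()
    flags = [
        (row.chrom, row.pos) in poly or (row.chrom, row.pos + 1) in poly
        for row in out[["chrom", "pos"]].itertuples(index=False)
    ]
    out["snp_cpg"] = flags
    return out


def cluster_heritable_cpgs(results: pd.DataFrame,
                           max_gap: int = 1000) -> pd.DataFrame:
    """Single-linkage clustering of heritable non-SNP CpGs.

    Consecutive heritable non-SNP CpGs on the same chromosome are merged
    while the inter-site distance is <= max_gap; singletons are kept.
    Returns one row per cluster: chrom, start, end, n_cpgs, cluster_id.
    """
    sel = results.loc[results["heritable"] & ~results["snp_cpg"],
                      ["chrom", "pos"]].sort_values(["chrom", "pos"])
    clusters = []
    for chrom, grp in sel.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        if len(pos) == 0:
            continue
        start = pos[0]
        prev = pos[0]
        count = 1
        for pcur in pos[1:]:
            if pcur - prev <= max_gap:
                count += 1
            else:
                clusters.append((chrom, int(start), int(prev), count))
                start, count = pcur, 1
            prev = pcur
        clusters.append((chrom, int(start), int(prev), count))
    out = pd.DataFrame(clusters, columns=["chrom", "start", "end", "n_cpgs"])
    out["cluster_id"] = [f"hclust{i}" for i in range(len(out))]
    return out


def run_mpo(m: MethylationMatrix, trios: TrioSet, genotypes: GenotypeMatrix,
            h2_min: float = 0.2, min_trios: int = 10, fdr: float = 0.05,
            cluster_max_gap: int = 1000) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full MPO stage: regression, heritable calls, SNP-CpG flags, clusters."""
    res = midparent_regression(m, trios)
    res = call_heritable_cpgs(res, h2_min=h2_min, min_trios=min_trios, fdr=fdr)
    res = classify_snp_cpg(res, genotypes)
    clusters = cluster_heritable_cpgs(res, max_gap=cluster_max_gap)
    return res, clusters
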