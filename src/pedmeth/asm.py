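"""Allele-specific methylation (ASM) from allele-tagged read fragments.

Within one individual, fragments spanning both a heterozygous SNP and a CpG
are tallied into a 2x2 table (allele x methylation state). ASM is called
when the two-sided Fisher exact p-value is below a cutoff and the absolute
between-allele methylation difference exceeds a minimum. Per-sample events
at the same CpG are then merged across individuals with a supporting-sample
count and a direction-consistency flag.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import AllelicFragmentSet, GenotypeMatrix

EVENT_COLUMNS = ["sample_id", "snp_id", "chrom", "cpg_pos",
                 "ref_meth", "ref_unmeth", "alt_meth", "alt_unmeth",
                 "frac_ref", "frac_alt", "delta", "p", "hypo_allele", "snp_cpg"]


def fisher_exact(table) -> float:
    """Two-sided Fisher exact p for a 2x2 count table.

    Point-probability rule: sums hypergeometric probabilities of all tables
    with the observed margins whose probability does not exceed the observed
    table's. A zero margin gives p = 1.
    """
    t = np.asarray(table)
    if t.shape != (2, 2) or (t < 0).any() or not np.issubdtype(t.dtype, np.integer):
        raise ValueError("table must be a 2x2 array of non-negative integers")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        return 1.0
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


def call_asm(frags: AllelicFragmentSet, p_max: float = 0.001,
             delta_min: float = 0.2, min_per_allele: int = 5,
             genotypes: GenotypeMatrix | None = None) -> pd.DataFrame:
    """Call per-sample ASM events from fragment records.

    One 2x2 table (allele x methylated) is built per (sample, SNP, CpG);
    an event is emitted iff p < p_max (strict) and
    |frac_ref - frac_alt| > delta_min (strict). Tables with fewer than
    ``min_per_allele`` fragments on either allele are skipped (the
    between-allele difference is too unstable to interpret). When a
    genotype matrix is given, events at CpGs whose dinucleotide carries a
    polymorphic SNP are flagged ``snp_cpg``.
    """
    rec = frags.records
    rows = []
    if len(rec):
        grouped = rec.groupby(["sample_id", "snp_id", "chrom", "cpg_pos"],
                              sort=True)
        for (sample, snp, chrom, cpg), grp in grouped:
            is_alt = grp["allele"].to_numpy() == "alt"
            meth = grp["methylated"].to_numpy().astype(bool)
            rm = int((meth & ~is_alt).sum())
            ru = int((~meth & ~is_alt).sum())
            am = int((meth & is_alt).sum())
            au = int((~meth & is_alt).sum())
            n_ref, n_alt = rm + ru, am + au
            if n_ref < min_per_allele or n_alt < min_per_allele:
                continue
            fr, fa = rm / n_ref, am / n_alt
            delta = abs(fr - fa)
            p = fisher_exact(np.array([[rm, ru], [am, au]]))
            if p < p_max and delta > delta_min:
                hypo = "alt" if fa < fr else ("ref" if fr < fa else "tie")
                rows.append((sample, snp, chrom, int(cpg), rm, ru, am, au,
                             fr, fa, delta, p, hypo, False))
    out = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    if genotypes is not None and len(out):
        poly = genotypes.polymorphic_positions()
        out["snp_cpg"] = [
            (c, p_) in poly or (c, p_ + 1) in poly
            for c, p_ in zip(out["chrom"], out["cpg_pos"])]
    return out


def merge_asm_events(events: pd.DataFrame) -> pd.DataFrame:
    """Merge per-sample ASM events into one record per CpG.

    ``support`` counts distinct samples; ``direction_consistent`` is true
    when every supporting sample agrees on which allele is hypomethylated.
    Merging is idempotent and independent of input order.
    """
    if len(events) == 0:
        return pd.DataFrame(columns=["chrom", "cpg_pos", "snp_ids", "support",
                                     "direction_consistent", "mean_delta",
                                     "min_p", "snp_cpg"])
    rows = []
    for (chrom, cpg), grp in events.groupby(["chrom", "cpg_pos"], sort=True):
        hypo = set(grp["hypo_allele"])
        rows.append({
            "chrom": chrom, "cpg_pos": int(cpg),
            "snp_ids": ",".join(sorted(set(grp["snp_id"]))),
            "support": int(grp["sample_id"].nunique()),
            "direction_consistent": len(hypo) == 1 and "tie" not in hypo,
            "mean_delta": float(grp["delta"].mean()),
            "min_p": float(grp["p"].min()),
            "snp_cpg": bool(grp["snp_cpg"].any()),
        })
    return pd.DataFrame(rows)
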