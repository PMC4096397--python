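"""Cross-method comparison and genomic-region annotation.

Compares the CpG sets called by the pedigree-based (MPO), population-based
(mQTL) and single-sample (ASM) analyses, summarizes CpG-SNP distance
distributions, and computes per-region-label enrichment of significant CpGs
against the analyzed background using BED half-open interval semantics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

CpGKey = tuple[str, int]  # (chrom, 1-based C position)


@dataclass
class OverlapResult:
    n_a: int
    n_b: int
    n_intersection: int
    frac_a_in_b: float  # NaN when |A| == 0
    frac_b_in_a: float  # NaN when |B| == 0


def overlap_fractions(set_a: set[CpGKey], set_b: set[CpGKey]) -> OverlapResult:
    """Exact set overlap between two CpG sets keyed by (chrom, pos).

    Fractions with an empty denominator are NaN (undefined), never 0.
    """
    inter = len(set_a & set_b)
    return OverlapResult(
        n_a=len(set_a), n_b=len(set_b), n_intersection=inter,
        frac_a_in_b=inter / len(set_a) if set_a else np.nan,
        frac_b_in_a=inter / len(set_b) if set_b else np.nan,
    )


def distance_distribution(associations: pd.DataFrame,
                          bin_edges: list[int]) -> pd.DataFrame:
    """Fraction of associations per |distance| bin.

    ``bin_edges`` are upper edges in bp; bins are (prev, edge] with the
    first bin starting at 0 inclusive. All |distance| values must fall
    within the last edge (the cis window). Fractions sum to 1.
    """
    if sorted(bin_edges) != list(bin_edges) or len(bin_edges) == 0:
        raise ValueError("bin_edges must be non-empty and increasing")
    if len(associations) == 0:
        return pd.DataFrame(columns=["upper_edge", "count", "fraction"])
    d = np.abs(associations["distance"].to_numpy())
    if (d > bin_edges[-1]).any():
        raise ValueError("association distance beyond the last bin edge "
                         "(cis window violation)")
    edges = np.array([0] + list(bin_edges), dtype=float)
    edges[0] = -0.5  # include distance 0 in the first bin
    counts, _ = np.histogram(d, bins=edges)
    return pd.DataFrame({"upper_edge": bin_edges, "count": counts,
                         "fraction": counts / counts.sum()})


def _build_trees(regions: pd.DataFrame) -> dict[str, dict[str, IntervalTree]]:
    """label -> chrom -> IntervalTree over 0-based half-open BED spans."""
    trees: dict[str, dict[str, IntervalTree]] = {}
    for row in regions.itertuples(index=False):
        if row.end <= row.start:
            continue
        trees.setdefault(row.label, {}).setdefault(
            row.chrom, IntervalTree()).addi(row.start, row.end)
    return trees


def annotate_cpgs(cpgs: set[CpGKey], regions: pd.DataFrame,
                  intergenic_label: str = "intergenic") -> pd.DataFrame:
    """Label membership per CpG; multi-label, with a fallback label for
    CpGs overlapping no interval.

    CpG 1-based position ``pos`` is converted to the 0-based half-open
    single-base interval [pos-1, pos): a CpG at BED start is inside, at
    BED end outside.
    """
    trees = _build_trees(regions)
    rows = []
    for chrom, pos in sorted(cpgs):
        hit = False
        for label, by_chrom in trees.items():
            tree = by_chrom.get(chrom)
            if tree is not None and tree.overlaps(pos - 1, pos):
                rows.append((chrom, pos, label))
                hit = True
        if not hit:
            rows.append((chrom, pos, intergenic_label))
    return pd.DataFrame(rows, columns=["chrom", "pos", "label"])


def annotate_enrichment(significant: set[CpGKey], background: set[CpGKey],
                        regions: pd.DataFrame,
                        intergenic_label: str = "intergenic") -> pd.DataFrame:
    """Per-label enrichment of significant CpGs over the analyzed background.

    ratio = (share of significant CpGs in the label) / (share of background
    CpGs in the label). Labels with zero background share get a NaN ratio;
    labels absent from both sets are omitted.
    """
    if not significant <= background:
        raise ValueError("significant CpGs must be a subset of the background")
    sig_ann = annotate_cpgs(significant, regions, intergenic_label)
    bg_ann = annotate_cpgs(background, regions, intergenic_label)
    labels = sorted(set(sig_ann["label"]) | set(bg_ann["label"]))
    rows = []
    for label in labels:
        fs = (sig_ann["label"] == label).sum() / len(significant) \
            if significant else np.nan
        fb = (bg_ann["label"] == label).sum() / len(background) \
            if background else np.nan
        ratio = fs / fb if (fb and fb > 0 and not np.isnan(fs)) else np.nan
        rows.append((label, fs, fb, ratio))
    return pd.DataFrame(rows, columns=["label", "frac_significant",
                                       "frac_background", "ratio"])


def comparison_report(mpo_results: pd.DataFrame, mqtl_results: pd.DataFrame,
                      asm_merged: pd.DataFrame,
                      fdr: float = 0.05) -> pd.DataFrame:
    """Pairwise overlap fractions between the three analyses' CpG sets,
    split by SNP-CpG status where available."""
    heritable = set(zip(mpo_results.loc[mpo_results["heritable"], "chrom"],
                        mpo_results.loc[mpo_results["heritable"], "pos"]))
    her_nonsnp = set(zip(
        mpo_results.loc[mpo_results["heritable"] & ~mpo_results["snp_cpg"], "chrom"],
        mpo_results.loc[mpo_results["heritable"] & ~mpo_results["snp_cpg"], "pos"]))
    sig = mqtl_results.loc[mqtl_results["q"] < fdr] if len(mqtl_results) else \
        mqtl_results
    mqtl_cpgs = set(zip(sig["chrom"], sig["cpg_pos"])) if len(sig) else set()
    asm_cpgs = set(zip(asm_merged["chrom"], asm_merged["cpg_pos"])) \
        if len(asm_merged) else set()

    rows = []
    for name_a, a, name_b, b in [
        ("mqtl", mqtl_cpgs, "heritable", heritable),
        ("mqtl", mqtl_cpgs, "heritable_non_snp", her_nonsnp),
        ("asm", asm_cpgs, "heritable", heritable),
        ("asm", asm_cpgs, "mqtl", mqtl_cpgs),
    ]:
        ov = overlap_fractions(a, b)
        rows.append((name_a, name_b, ov.n_a, ov.n_b, ov.n_intersection,
                     ov.frac_a_in_b, ov.frac_b_in_a))
    return pd.DataFrame(rows, columns=["set_a", "set_b", "n_a", "n_b",
                                       "n_intersection", "frac_a_in_b",
                                       "frac_b_in_a"])
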