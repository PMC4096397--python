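"""Shared fixtures and independent oracles.

The oracle functions here are deliberately naive (full enumeration,
closed-form arithmetic) and never call the implementation they check.
"""

from __future__ import annotations

from math import comb

import numpy as np
import pandas as pd
import pytest

from pedmeth.containers import MethylationMatrix


# ------------------------------------------------------------------ oracles

def fisher_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p by full hypergeometric enumeration."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0
    denom = comb(n, c1)

    def prob(x: int) -> float:
        if x < 0 or x > r1 or c1 - x < 0 or c1 - x > r2:
            return 0.0
        return comb(r1, x) * comb(r2, c1 - x) / denom

    p_obs = prob(a)
    total = 0.0
    for x in range(0, min(r1, c1) + 1):
        px = prob(x)
        if px <= p_obs * (1 + 1e-9):
            total += px
    return min(total, 1.0)


def hwe_oracle(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact HWE p by enumeration over heterozygote counts."""
    n = n_aa + n_ab + n_bb
    n_alt = 2 * n_bb + n_ab
    if n_alt == 0 or n_alt == 2 * n:
        return 1.0
    probs = {}
    for h in range(n_alt % 2, min(n_alt, 2 * n - n_alt) + 1, 2):
        a_ = (n_alt - h) // 2
        r_ = n - h - a_
        # unnormalized Levene-Haldane weight
        w = comb(n, h) * comb(n - h, a_) * 2 ** h
        probs[h] = w
    z = sum(probs.values())
    p_obs = probs[n_ab] / z
    return min(sum(w / z for w in probs.values()
                   if w / z <= p_obs * (1 + 1e-9)), 1.0)


def bh_oracle(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, from the definition."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = p[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest rank down
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def ols_slope_oracle(x, y) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return float(np.sum((x - x.mean()) * (y - y.mean()))
                 / np.sum((x - x.mean()) ** 2))


# ----------------------------------------------------------------- fixtures

def make_matrix(values, chrom="chr1", start=100, spacing=1000,
                depth=100) -> MethylationMatrix:
    """Methylation matrix from a (sites x samples) array, evenly spaced."""
    values = np.asarray(values, dtype=float)
    n_sites, n_samples = values.shape
    sites = pd.DataFrame({"chrom": chrom,
                          "pos": start + spacing * np.arange(n_sites),
                          "strand": "+"})
    samples = [f"s{j}" for j in range(n_samples)]
    depths = np.full(values.shape, depth, dtype=int)
    return MethylationMatrix(sites, samples, values, depths)


@pytest.fixture(scope="session")
def demo_cohort():
    """One seeded mixed-effect cohort shared by read-only tests."""
    from pedmeth.synthetic import (DEFAULT_FAMILY_CHILD_COUNTS, EffectConfig,
                                   simulate_allelic_fragments, simulate_cohort,
                                   simulate_methylome)
    eff = EffectConfig(
        n_snps=15, n_cpgs=40, seed=11, read_depth=80,
        snp_cpg_sites=[(0, 0), (1, 1)],
        cis_effects=[(2, 4, 0.15), (3, 6, -0.12)],
        vsnp_effects=[(4, tuple(range(10, 18)), 0.02, 0.08, 0.15)],
        family_noise_cpgs=[20, 21],
    )
    ped, g = simulate_cohort(22, DEFAULT_FAMILY_CHILD_COUNTS, eff)
    m, truth = simulate_methylome(ped, g, eff)
    frags = simulate_allelic_fragments(g, truth, depth=25, seed=11)
    return eff, ped, g, m, truth, frags
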