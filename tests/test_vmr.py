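"""Variance regression, VMR run-calling rules, permutation FPR estimation
and VMR clustering."""

import numpy as np
import pandas as pd
import pytest

from pedmeth.synthetic import EffectConfig, simulate_cohort, simulate_methylome
from pedmeth.vmr import (call_vmrs, choose_t_min_by_fpr, cluster_vmrs,
                         estimate_fpr_by_permutation, variance_regression,
                         variance_scan, _three_point_slope_t)
from .conftest import make_matrix


def groups_vector(v0, v1, v2, n=10, sd=0.0, rng=None):
    """y/dosage vectors with n samples per genotype class at given SDs."""
    rng = rng or np.random.default_rng(0)
    y, d = [], []
    for code, sigma in zip((0, 1, 2), (v0, v1, v2)):
        y.extend(0.5 + rng.normal(0, sigma, n))
        d.extend([code] * n)
    return np.array(y), np.array(d, dtype=float)


class TestVarianceRegression:
    def test_equal_variances_give_zero_slope(self):
        slope, t = _three_point_slope_t(np.array([0.03, 0.03, 0.03]))
        assert slope == 0.0
        assert t == 0.0

    def test_closed_form_slope(self):
        # variances [0.01, 0.04, 0.09] on codes 0,1,2: slope = 0.08/2
        slope, _ = _three_point_slope_t(np.array([0.01, 0.04, 0.09]))
        assert slope == pytest.approx(0.04)

    def test_group_below_min_n_untestable(self):
        y, d = groups_vector(0.02, 0.05, 0.1, n=5)
        d[d == 1] = 0.0
        d[5] = 1.0  # AB group with 1 sample
        assert variance_regression(y, d, min_group_n=3) is None

    def test_two_genotype_groups_untestable(self):
        y, d = groups_vector(0.02, 0.05, 0.1, n=5)
        d[d == 2] = 0.0
        assert variance_regression(y, d, min_group_n=3) is None

    def test_recovers_variance_trend(self):
        rng = np.random.default_rng(7)
        y, d = groups_vector(0.02, 0.08, 0.15, n=200, rng=rng)
        slope, t = variance_regression(y, d)
        assert slope > 0
        assert t > 2


def score_frame(positions, ts, snp="snpA", slopes=None):
    slopes = slopes if slopes is not None else np.sign(ts) * 0.01
    return pd.DataFrame({"chrom": "chr1", "cpg_pos": positions,
                         "snp_id": snp, "snp_pos": 10, "slope": slopes,
                         "t": ts})


class TestCallVmrs:
    def test_four_qualifying_cpgs_insufficient(self):
        scores = score_frame([100, 200, 300, 400], [3.0] * 4)
        assert len(call_vmrs(scores, t_min=2.0, min_cpgs=5,
                             max_spacing=200)) == 0

    def test_spacing_gap_breaks_run(self):
        # five qualifying CpGs but one 201 bp gap
        scores = score_frame([100, 200, 300, 501, 601], [3.0] * 5)
        assert len(call_vmrs(scores, t_min=2.0, min_cpgs=5,
                             max_spacing=200)) == 0

    def test_six_consistent_cpgs_form_one_vmr(self):
        scores = score_frame([100 + 100 * i for i in range(6)], [3.0] * 6)
        out = call_vmrs(scores, t_min=2.0, min_cpgs=5, max_spacing=200)
        assert len(out) == 1
        assert out.at[0, "n_cpgs"] == 6
        assert out.at[0, "start"] == 100 and out.at[0, "end"] == 600

    def test_sign_flip_breaks_run(self):
        ts = [3.0, 3.0, 3.0, -3.0, 3.0, 3.0]
        scores = score_frame([100 + 100 * i for i in range(6)], ts)
        assert len(call_vmrs(scores, t_min=2.0, min_cpgs=5,
                             max_spacing=200)) == 0

    def test_weak_site_breaks_run(self):
        ts = [3.0, 3.0, 1.0, 3.0, 3.0, 3.0]
        scores = score_frame([100 + 100 * i for i in range(6)], ts)
        assert len(call_vmrs(scores, t_min=2.0, min_cpgs=5,
                             max_spacing=200)) == 0

    def test_empty_scores(self):
        assert len(call_vmrs(score_frame([], []), 2.0)) == 0


class TestClusterVmrs:
    def vmr_frame(self, spans, snps=None):
        snps = snps or [f"snp{i}" for i in range(len(spans))]
        return pd.DataFrame({"snp_id": snps, "chrom": "chr1",
                             "start": [s for s, _ in spans],
                             "end": [e for _, e in spans],
                             "n_cpgs": 5, "cpg_positions": "",
                             "direction": 1, "t_scores": ""})

    def test_within_100kb_merges(self):
        vmrs = self.vmr_frame([(1000, 2000), (101_000, 102_000)])
        out = cluster_vmrs(vmrs, max_distance=100_000)
        assert len(out) == 1
        assert out.at[0, "n_vmrs"] == 2

    def test_beyond_100kb_stays_separate(self):
        vmrs = self.vmr_frame([(1000, 2000), (103_001, 104_000)])
        out = cluster_vmrs(vmrs, max_distance=100_000)
        assert len(out) == 2

    def test_single_vmr_single_cluster(self):
        out = cluster_vmrs(self.vmr_frame([(1000, 2000)]))
        assert len(out) == 1

    def test_overlapping_vmrs_from_different_vsnps_merge(self):
        vmrs = self.vmr_frame([(1000, 3000), (2000, 4000)], ["snpA", "snpB"])
        out = cluster_vmrs(vmrs, max_distance=100_000)
        assert len(out) == 1
        assert out.at[0, "snp_ids"] == "snpA,snpB"

    def test_order_independent_and_idempotent(self):
        vmrs = self.vmr_frame([(1000, 2000), (50_000, 51_000),
                               (500_000, 501_000)])
        a = cluster_vmrs(vmrs)
        b = cluster_vmrs(vmrs.iloc[::-1].reset_index(drop=True))
        pd.testing.assert_frame_equal(a, b)
        spans = a.rename(columns={"cluster_id": "snp_id"})
        spans["snp_id"] = [f"snp{i}" for i in range(len(spans))]
        spans["n_cpgs"] = 5
        again = cluster_vmrs(spans)
        assert len(again) == len(a)


def planted_cohort(seed, with_effect=True, n_samples_families=100):
    sigmas = (0.02, 0.08, 0.15) if with_effect else (0.05, 0.05, 0.05)
    eff = EffectConfig(n_snps=6, n_cpgs=30, seed=seed, read_depth=None,
                       maf_range=(0.3, 0.5), residual_sd=0.05,
                       vsnp_effects=[(0, tuple(range(10, 18)), *sigmas)],
                       baseline_beta=(8.0, 8.0))
    ped, g = simulate_cohort(n_samples_families, 0, eff)
    m, truth = simulate_methylome(ped, g, eff)
    return m, g, truth


class TestFprEstimation:
    def test_ratio_arithmetic_and_determinism(self):
        m, g, truth = planted_cohort(5)
        est1 = estimate_fpr_by_permutation(m, g, t_min=2.0, n_perm=4, seed=3)
        est2 = estimate_fpr_by_permutation(m, g, t_min=2.0, n_perm=4, seed=3)
        assert est1 == est2
        assert est1.observed_calls >= 1
        assert est1.fpr == pytest.approx(
            est1.mean_permuted_calls / est1.observed_calls)
        assert est1.mean_permuted_calls == pytest.approx(
            np.mean(est1.per_permutation_calls))

    def test_no_observed_calls_reports_counts_only(self):
        m, g, _ = planted_cohort(6, with_effect=False, n_samples_families=30)
        est = estimate_fpr_by_permutation(m, g, t_min=50.0, n_perm=2, seed=1)
        assert est.observed_calls == 0
        assert np.isnan(est.fpr)

    def test_null_cohort_observed_matches_permuted(self):
        """With no variance effects, observed and permuted call counts are
        statistically indistinguishable (conditional binomial test)."""
        from scipy import stats
        n_cohorts, n_perm = 6, 3
        obs_total, perm_total = 0, 0
        for seed in range(n_cohorts):
            m, g, _ = planted_cohort(100 + seed, with_effect=False)
            est = estimate_fpr_by_permutation(m, g, t_min=2.0, n_perm=n_perm,
                                              seed=seed)
            obs_total += est.observed_calls
            perm_total += sum(est.per_permutation_calls)
        total = obs_total + perm_total
        if total > 0:
            # each call lands in an observed run with prob N/(N+M) under null
            p = stats.binomtest(obs_total, total,
                                n_cohorts / (n_cohorts + n_cohorts * n_perm)
                                ).pvalue
            assert p > 0.01


def test_calibrated_cutoff_controls_fpr():
    m, g, truth = planted_cohort(9)
    t_min = choose_t_min_by_fpr(m, g, fpr_target=0.10, n_perm=5, seed=2)
    est = estimate_fpr_by_permutation(m, g, t_min, n_perm=5, seed=2)
    if est.observed_calls > 0:
        assert est.fpr <= 0.10 + 1e-9


def test_planted_vsnp_block_recovered():
    m, g, truth = planted_cohort(12, n_samples_families=100)
    scores = variance_scan(m, g)
    vmrs = call_vmrs(scores, t_min=2.0)
    block = truth.vsnp_blocks[0]
    hit = vmrs[(vmrs["snp_id"] == block["snp_id"]) & (vmrs["n_cpgs"] >= 5)]
    assert len(hit) >= 1
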