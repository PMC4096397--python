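"""SNP QC (MAF/HWE/Mendel), BH FDR, and the cis-mQTL scan with
family-aware permutations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pedmeth.containers import GenotypeMatrix, PedigreeSet, TrioSet
from pedmeth.mqtl import (bh_fdr, family_permutations, hwe_test, mendel_errors,
                          mqtl_scan, snp_qc)
from .conftest import bh_oracle, hwe_oracle, make_matrix


def geno(positions, dosage_rows, chrom="chr1"):
    snps = pd.DataFrame({"id": [f"snp{i}" for i in range(len(positions))],
                         "chrom": chrom, "pos": positions,
                         "ref": "A", "alt": "G"})
    samples = [f"s{j}" for j in range(len(dosage_rows[0]))]
    return GenotypeMatrix(snps, samples, np.array(dosage_rows, dtype=float))


class TestHwe:
    def test_perfect_hwe_proportions(self):
        assert hwe_test(25, 50, 25) > 0.5

    def test_against_enumeration_oracle(self):
        assert hwe_test(3, 0, 3) == pytest.approx(hwe_oracle(3, 0, 3), abs=1e-12)

    def test_monomorphic_is_one(self):
        assert hwe_test(0, 0, 10) == 1.0
        assert hwe_test(10, 0, 0) == 1.0

    @given(st.integers(0, 12), st.integers(0, 12), st.integers(0, 12))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_matches_oracle_everywhere(self, aa, ab, bb):
        if aa + ab + bb == 0:
            return
        assert hwe_test(aa, ab, bb) == pytest.approx(
            hwe_oracle(aa, ab, bb), abs=1e-12)


class TestBh:
    def test_hand_example(self):
        q = bh_fdr([0.01, 0.04, 0.03, 0.005])
        np.testing.assert_allclose(q, [0.02, 0.04, 0.04, 0.02])

    def test_all_ones(self):
        np.testing.assert_allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_single_p(self):
        assert bh_fdr([0.37])[0] == pytest.approx(0.37)

    def test_empty(self):
        assert len(bh_fdr([])) == 0

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_matches_step_up_oracle(self, pvals):
        np.testing.assert_allclose(bh_fdr(pvals), bh_oracle(pvals), atol=1e-12)


class TestSnpQc:
    def test_maf_arithmetic(self):
        # dosages [0,0,1,2]: alt freq 3/8 -> MAF 0.375, kept at 0.05
        g = geno([100], [[0, 0, 1, 2]])
        filtered, _ = snp_qc(g, TrioSet([]), maf_min=0.05, hwe_min_p=0.0)
        assert filtered.n_snps == 1

    def test_low_maf_removed(self):
        # 1 alt allele in 25 samples: MAF 0.02 < 0.05
        g = geno([100], [[1] + [0] * 24])
        filtered, _ = snp_qc(g, TrioSet([]), maf_min=0.05, hwe_min_p=0.0)
        assert filtered.n_snps == 0

    def test_hwe_violation_removed(self):
        # all heterozygous: gross HWE violation at n=40
        g = geno([100], [[1] * 40])
        filtered, _ = snp_qc(g, TrioSet([]), maf_min=0.05, hwe_min_p=0.001)
        assert filtered.n_snps == 0

    def test_mendel_error_counted(self):
        g = geno([100], [[0, 0, 1]])
        trios = TrioSet([("s0", "s1", "s2")])
        report = mendel_errors(g, trios)
        assert report["n_errors"].sum() == 1

    def test_possible_transmission_not_error(self):
        g = geno([100], [[1, 0, 1]])
        report = mendel_errors(g, TrioSet([("s0", "s1", "s2")]))
        assert report["n_errors"].sum() == 0

    def test_all_filtered_warns_empty(self, caplog):
        g = geno([100], [[0, 0, 0, 0]])
        with caplog.at_level("WARNING"):
            filtered, _ = snp_qc(g, TrioSet([]), maf_min=0.05, hwe_min_p=0.001)
        assert filtered.n_snps == 0
        assert any("filtered" in r.message for r in caplog.records)


class TestFamilyPermutations:
    def test_blocks_are_preserved(self):
        ped = PedigreeSet(pd.DataFrame({
            "sample_id": ["a1", "a2", "b1", "b2", "c1"],
            "family_id": ["A", "A", "B", "B", "C"],
            "father_id": [None] * 5, "mother_id": [None] * 5,
            "sex": [1, 2, 1, 2, 1]}))
        samples = ["a1", "a2", "b1", "b2", "c1"]
        P = family_permutations(samples, ped, 50, np.random.default_rng(0))
        y = np.array([10.0, 11.0, 20.0, 21.0, 30.0])
        fam_sets = [{10.0, 11.0}, {20.0, 21.0}]
        for k in range(50):
            yp = y[P[k]]
            # each size-2 family slot holds exactly one family's values
            assert {yp[0], yp[1]} in fam_sets
            assert {yp[2], yp[3]} in fam_sets
            assert yp[4] == 30.0  # singleton block can only map to itself


class TestScan:
    def make_inputs(self, snp_offset, n=6):
        rng = np.random.default_rng(0)
        m = make_matrix(rng.random((1, n)), start=1000)
        g = geno([1000 + snp_offset], [list(rng.integers(0, 3, n))])
        return m, g

    def test_window_boundary(self):
        m, g = self.make_inputs(1_000_001)
        out = mqtl_scan(m, g, None, window=1_000_000, n_perm=0)
        assert len(out) == 0
        m, g = self.make_inputs(1_000_000)
        out = mqtl_scan(m, g, None, window=1_000_000, n_perm=0)
        assert len(out) == 1

    def test_closed_form_slope(self):
        m = make_matrix([[0.1, 0.2, 0.3]], start=1000)
        g = geno([1500], [[0, 1, 2]])
        out = mqtl_scan(m, g, None, window=10_000, n_perm=0)
        assert out.at[0, "beta"] == pytest.approx(0.1)
        assert out.at[0, "distance"] == 500

    def test_zero_genotype_variance_skipped(self):
        m = make_matrix([[0.1, 0.2, 0.3, 0.4]], start=1000)
        g = geno([1500], [[1, 1, 1, 1]])
        assert len(mqtl_scan(m, g, None, window=10_000, n_perm=0)) == 0

    def test_fewer_than_three_complete_obs_skipped(self):
        m = make_matrix([[0.1, 0.2, np.nan, np.nan]], start=1000)
        g = geno([1500], [[0, 1, 2, 2]])
        assert len(mqtl_scan(m, g, None, window=10_000, n_perm=0)) == 0

    def test_n_perm_zero_leaves_empirical_empty(self):
        m = make_matrix([[0.1, 0.2, 0.3, 0.25, 0.15]], start=1000)
        g = geno([1500], [[0, 1, 2, 1, 0]])
        out = mqtl_scan(m, g, None, window=10_000, n_perm=0)
        assert np.isnan(out.at[0, "p_emp"])
        assert not np.isnan(out.at[0, "p_asym"])

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(5)
        m = make_matrix(rng.random((3, 12)), start=1000)
        g = geno([1200, 2500], [list(rng.integers(0, 3, 12)) for _ in range(2)])
        a = mqtl_scan(m, g, None, window=10_000, n_perm=50, seed=9)
        b = mqtl_scan(m, g, None, window=10_000, n_perm=50, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_empirical_matches_asymptotic_for_unrelated_samples(self):
        """With no family structure and a strong effect, permutation and
        asymptotic p agree on significance."""
        rng = np.random.default_rng(3)
        n = 60
        d = rng.integers(0, 3, n).astype(float)
        y = 0.4 + 0.1 * d + rng.normal(0, 0.05, n)
        m = make_matrix(np.clip(y, 0, 1)[None, :], start=1000)
        g = geno([1500], [list(d)])
        out = mqtl_scan(m, g, None, window=10_000, n_perm=500, seed=1)
        assert out.at[0, "p_asym"] < 1e-6
        assert out.at[0, "p_emp"] == 0.0

    def test_widening_window_never_drops_pairs(self):
        rng = np.random.default_rng(8)
        m = make_matrix(rng.random((4, 10)), start=1000, spacing=50_000)
        g = geno([1000, 90_000, 220_000],
                 [list(rng.integers(0, 3, 10)) for _ in range(3)])
        narrow = mqtl_scan(m, g, None, window=50_000, n_perm=0)
        wide = mqtl_scan(m, g, None, window=500_000, n_perm=0)
        narrow_keys = set(zip(narrow["cpg_pos"], narrow["snp_id"]))
        wide_keys = set(zip(wide["cpg_pos"], wide["snp_id"]))
        assert narrow_keys <= wide_keys
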