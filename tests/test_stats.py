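"""Permutation Welch testing, eligibility, and permutation FDR."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import glycodiff as gd
from glycodiff.stats import permutation_null

from conftest import (
    brute_force_perm_p,
    quant_matrix_from_values,
    welch_t_oracle,
)

finite_floats = st.floats(-100, 100)


class TestWelchT:
    def test_identical_samples_give_zero(self):
        assert gd.welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_closed_form_example(self):
        expected = -3.0 / math.sqrt(2.0 / 3.0)
        assert gd.welch_t([1, 2, 3], [4, 5, 6]) == pytest.approx(expected)

    def test_zero_variance_equal_means_is_zero(self):
        assert gd.welch_t([2.0, 2.0], [2.0, 2.0]) == 0.0

    def test_zero_variance_unequal_means_is_signed_infinity(self):
        assert gd.welch_t([3.0, 3.0], [1.0, 1.0]) == math.inf
        assert gd.welch_t([1.0, 1.0], [3.0, 3.0]) == -math.inf

    def test_requires_two_per_group(self):
        with pytest.raises(ValueError):
            gd.welch_t([1.0], [1.0, 2.0])

    @given(
        st.lists(finite_floats, min_size=2, max_size=8),
        st.lists(finite_floats, min_size=2, max_size=8),
        st.floats(0.1, 50),
    )
    def test_scaling_both_samples_preserves_magnitude(self, x, y, c):
        t0 = gd.welch_t(x, y)
        t1 = gd.welch_t([c * v for v in x], [c * v for v in y])
        if math.isfinite(t0):
            assert abs(t1) == pytest.approx(abs(t0), abs=1e-9)

    @given(
        st.lists(finite_floats, min_size=2, max_size=8),
        st.lists(finite_floats, min_size=2, max_size=8),
    )
    def test_matches_plain_python_oracle(self, x, y):
        t = gd.welch_t(x, y)
        oracle = welch_t_oracle(x, y)
        if math.isfinite(oracle):
            assert t == pytest.approx(oracle, abs=1e-9)
        else:
            assert t == oracle


class TestPermutationPvalue:
    def test_all_identical_values_give_p_one(self):
        assert gd.permutation_pvalue([5.0] * 3, [5.0] * 3) == 1.0

    def test_separated_groups_brute_force_example(self):
        # C(6,3)=20 relabelings; only the observed split and its mirror
        # reach |t_obs|
        p = gd.permutation_pvalue([1, 2, 3], [10, 11, 12])
        assert p == 2 / 20

    def test_monte_carlo_agrees_with_exhaustive(self):
        x, y = [1.0, 2.0, 3.0, 2.5], [4.0, 5.0, 3.5, 6.0]
        exact = gd.permutation_pvalue(x, y)
        mc = gd.permutation_pvalue(x, y, n_perm=10_000, seed=77, cap=1)
        tol = 3 * math.sqrt(exact * (1 - exact) / 10_000) + 2e-4
        assert abs(mc - exact) < tol

    def test_monte_carlo_never_returns_zero(self):
        p = gd.permutation_pvalue([0.0] * 5, [100.0] * 5, n_perm=200, seed=1, cap=1)
        assert p >= 1 / 201

    def test_label_swap_leaves_p_unchanged(self):
        x, y = [0.3, 1.2, -0.5, 0.8], [1.5, 2.2, 0.9]
        assert gd.permutation_pvalue(x, y) == gd.permutation_pvalue(y, x)

    def test_exhaustive_null_includes_all_relabelings(self):
        null, exhaustive = permutation_null([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert exhaustive and null.size == 20


class TestEligibility:
    def test_boundary_three_per_group_is_eligible(self):
        qm = quant_matrix_from_values(
            {("A", "UNB"): {f"BPH_{i}": 0.1 * i for i in range(3)}
             | {f"PCa_{i}": 0.2 * i for i in range(3)}}
        )
        out = gd.eligibility_filter(qm)
        assert out.loc[0, "eligible"]
        assert out.loc[0, "n_bph"] == 3 and out.loc[0, "n_pca"] == 3

    def test_two_in_one_group_is_ineligible(self):
        qm = quant_matrix_from_values(
            {("A", "UNB"): {f"BPH_{i}": 0.1 * i for i in range(2)}
             | {f"PCa_{i}": 0.2 * i for i in range(10)}}
        )
        assert not gd.eligibility_filter(qm).loc[0, "eligible"]

    def test_absent_group_is_ineligible(self):
        qm = quant_matrix_from_values(
            {("A", "PHA"): {f"PCa_{i}": 0.2 * i for i in range(5)}}
        )
        out = gd.eligibility_filter(qm)
        assert not out.loc[0, "eligible"]
        assert out.loc[0, "n_bph"] == 0


class TestPermutationFdr:
    def test_feature_below_all_permuted_p_gets_zero(self):
        perm = np.full((50, 1), 0.5)
        fdr, raw = gd.permutation_fdr([0.01], perm)
        assert fdr[0] == 0.0 and raw[0] == 0.0

    def test_monotone_in_p(self):
        rng = np.random.default_rng(3)
        obs = rng.uniform(size=40)
        perm = rng.uniform(size=(30, 40))
        fdr, _ = gd.permutation_fdr(obs, perm)
        order = np.argsort(obs)
        assert np.all(np.diff(fdr[order]) >= -1e-15)

    def test_empty_input_gives_empty_output(self):
        fdr, raw = gd.permutation_fdr([], np.empty((10, 0)))
        assert fdr.size == 0 and raw.size == 0

    def test_null_simulation_rarely_passes_one_percent_bound(self):
        """Under a pure null, ~no features should reach FDR <= 0.01."""
        rng = np.random.default_rng(19)
        hits = total = 0
        for _ in range(50):
            obs = rng.uniform(size=100)
            perm = rng.uniform(size=(40, 100))
            fdr, _ = gd.permutation_fdr(obs, perm)
            hits += int((fdr <= 0.01).sum())
            total += obs.size
        assert hits / total <= 0.02

    def test_values_clipped_to_unit_interval(self):
        rng = np.random.default_rng(5)
        obs = rng.uniform(size=25)
        perm = rng.uniform(size=(10, 25))
        fdr, raw = gd.permutation_fdr(obs, perm)
        for v in (fdr, raw):
            assert np.all((v >= 0) & (v <= 1))


class TestCompareGroups:
    def make_matrix(self, pca_vals, bph_vals, gene="SPARC", level="UNB"):
        return quant_matrix_from_values(
            {(gene, level): (
                {f"PCa_{i + 1}": v for i, v in enumerate(pca_vals)}
                | {f"BPH_{i + 1}": v for i, v in enumerate(bph_vals)}
            )}
        )

    def test_delta_is_difference_of_group_means(self):
        # group means engineered to the reported SPARC UNB example values
        pca = [2.58 - 0.3, 2.58, 2.58 + 0.3, 2.58 - 0.1, 2.58 + 0.1]
        bph = [1.58 - 0.2, 1.58, 1.58 + 0.2]
        out = gd.compare_groups(self.make_matrix(pca, bph), seed=0)
        row = out.iloc[0]
        assert row["mean_pca"] == pytest.approx(2.58)
        assert row["mean_bph"] == pytest.approx(1.58)
        assert row["delta"] == pytest.approx(1.00)

    def test_cd163_style_delta(self):
        pca = [0.373 - 0.1, 0.373, 0.373 + 0.1]
        bph = [-0.610 - 0.1, -0.610, -0.610 + 0.1]
        out = gd.compare_groups(
            self.make_matrix(pca, bph, gene="CD163", level="PHA"), seed=0
        )
        assert out.iloc[0]["delta"] == pytest.approx(0.983)

    def test_identical_groups_give_zero_delta_p_one(self):
        vals = [0.5, 1.0, 1.5]
        out = gd.compare_groups(self.make_matrix(vals, vals), seed=0)
        row = out.iloc[0]
        assert row["delta"] == pytest.approx(0.0)
        assert row["p_value"] == 1.0

    def test_group_swap_negates_delta_keeps_p(self):
        rng = np.random.default_rng(8)
        pca = list(rng.normal(1.0, 0.5, 6))
        bph = list(rng.normal(0.0, 0.5, 5))
        fwd = gd.compare_groups(self.make_matrix(pca, bph), seed=4).iloc[0]
        rev = gd.compare_groups(self.make_matrix(bph, pca), seed=4).iloc[0]
        assert rev["delta"] == pytest.approx(-fwd["delta"])
        assert rev["p_value"] == pytest.approx(fwd["p_value"])

    def test_ineligible_features_keep_means_but_no_p(self):
        qm = quant_matrix_from_values(
            {("A", "AAL"): {"PCa_1": 1.0, "PCa_2": 1.2, "PCa_3": 0.8,
                            "BPH_1": 0.1, "BPH_2": 0.3}}
        )
        row = gd.compare_groups(qm, seed=0).iloc[0]
        assert not row["eligible"]
        assert row["mean_pca"] == pytest.approx(1.0)
        assert np.isnan(row["p_value"]) and np.isnan(row["fdr"])

    def test_fc_flag_uses_pca_group_mean_magnitude(self):
        high = self.make_matrix([0.7, 0.6, 0.8], [0.0, 0.1, -0.1])
        low = self.make_matrix([0.3, 0.2, 0.4], [0.0, 0.1, -0.1])
        down = self.make_matrix([-0.7, -0.6, -0.8], [0.0, 0.1, -0.1])
        assert gd.compare_groups(high, seed=0).iloc[0]["fc_flag"]
        assert not gd.compare_groups(low, seed=0).iloc[0]["fc_flag"]
        assert gd.compare_groups(down, seed=0).iloc[0]["fc_flag"]

    def test_deterministic_given_seed(self, small_effect_design):
        evidence, _ = gd.generate_cohort(small_effect_design)
        qm, _ = gd.build_quant_matrix(evidence)
        a = gd.compare_groups(qm, seed=9, n_perm_fdr=50)
        b = gd.compare_groups(qm, seed=9, n_perm_fdr=50)
        pd.testing.assert_frame_equal(a, b)

    def test_missingness_respecting_counts(self, small_effect_design):
        evidence, _ = gd.generate_cohort(small_effect_design)
        qm, _ = gd.build_quant_matrix(evidence)
        out = gd.compare_groups(qm, seed=2, n_perm_fdr=20)
        elig = gd.eligibility_filter(qm).set_index(["gene", "level"])
        for _, row in out.iterrows():
            ref = elig.loc[(row["gene"], row["level"])]
            assert row["n_bph"] == ref["n_bph"]
            assert row["n_pca"] == ref["n_pca"]


class TestOracleEquivalence:
    @pytest.mark.parametrize("nx,ny,seed", [(3, 3, 0), (4, 3, 1), (5, 4, 2),
                                            (6, 6, 3), (2, 10, 4), (3, 9, 5)])
    def test_exhaustive_matches_brute_force(self, nx, ny, seed):
        rng = np.random.default_rng(seed)
        x = list(rng.normal(0.5, 1.0, nx))
        y = list(rng.normal(0.0, 1.0, ny))
        assert gd.permutation_pvalue(x, y) == brute_force_perm_p(x, y)

    def test_brute_force_agreement_with_ties(self):
        x, y = [1.0, 1.0, 2.0], [1.0, 2.0, 2.0]
        assert gd.permutation_pvalue(x, y) == brute_force_perm_p(x, y)
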