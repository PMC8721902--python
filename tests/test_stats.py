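"""Rank-sum enumeration, bootstrap SEM, z-comparison, ΔΔCt transform."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from ictalfp.stats import (
    bootstrap_mean,
    bootstrap_z_comparison,
    compare_groups,
    ddct_fold_change,
    ranksum_test,
    signed_rank_test,
)


class TestRankSum:
    def test_identical_samples_give_p_one(self):
        _, p = ranksum_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0)

    def test_complete_separation_exact_p(self):
        """{1,2,3} vs {4,5,6}: two-sided exact p = 2/C(6,3) = 0.1."""
        w, p = ranksum_test([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert w == 6.0  # ranks 1+2+3
        assert p == pytest.approx(0.1)

    def test_empty_input_raises(self):
        with pytest.raises(ValueError, match="nonempty"):
            ranksum_test([], [1.0])

    def test_cohort_shape_accepted(self):
        """The n=6 vs n=10 cohort comparison shape runs exact."""
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=6), rng.normal(1.0, size=10)
        _, p = ranksum_test(a, b)
        assert 0 < p <= 1

    @pytest.mark.parametrize("n_a,n_b", [(2, 3), (3, 3), (4, 5), (5, 6), (6, 6)])
    def test_exact_agrees_with_independent_oracle(self, n_a, n_b):
        """Enumeration matches scipy's exact Mann-Whitney p for tie-free data."""
        rng = np.random.default_rng(n_a * 10 + n_b)
        for _ in range(5):
            pooled = rng.permutation(np.arange(1.0, n_a + n_b + 1))
            a, b = pooled[:n_a], pooled[n_a:]
            _, p_mine = ranksum_test(a, b)
            p_scipy = sps.mannwhitneyu(
                a, b, alternative="two-sided", method="exact"
            ).pvalue
            assert p_mine == pytest.approx(p_scipy, abs=1e-12)

    def test_tied_data_uses_corrected_normal_approximation(self):
        a = [1.0, 2.0, 2.0, 3.0]
        b = [2.0, 4.0, 4.0, 5.0]
        _, p = ranksum_test(a, b)
        p_scipy = sps.mannwhitneyu(a, b, alternative="two-sided",
                                   method="asymptotic").pvalue
        assert p == pytest.approx(p_scipy)

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(
        st.integers(2, 5),
        st.integers(2, 5),
        st.randoms(use_true_random=False),
    )
    def test_exact_p_is_valid_probability(self, n_a, n_b, rnd):
        pooled = list(range(1, n_a + n_b + 1))
        rnd.shuffle(pooled)
        a = [float(v) for v in pooled[:n_a]]
        b = [float(v) for v in pooled[n_a:]]
        _, p = ranksum_test(a, b)
        assert 0 < p <= 1


def test_signed_rank_wrapper_runs():
    stat, p = signed_rank_test([1.0, 2.0, 3.5, 4.0], [2.0, 3.0, 1.0, 6.0])
    assert 0 < p <= 1


class TestBootstrap:
    def test_constant_data_gives_zero_sem(self):
        res = bootstrap_mean([5.0, 5.0, 5.0, 5.0], seed=0)
        assert np.all(res.resampled_means == 5.0)
        assert res.sem_gaussian_fit == 0.0

    def test_default_resample_count(self):
        res = bootstrap_mean([1.0, 2.0, 3.0], seed=0)
        assert res.n_resamples == 10_000
        assert res.resampled_means.size == 10_000

    def test_sem_matches_analytic_for_standard_normal(self):
        """n=100 standard normal: Gaussian-fit SEM within 15% of 0.1."""
        rng = np.random.default_rng(123)
        data = rng.standard_normal(100)
        res = bootstrap_mean(data, 10_000, seed=5)
        assert res.sem_gaussian_fit == pytest.approx(0.1, rel=0.15)
        # the two Gaussian fits agree for unimodal data
        assert res.sem_histogram_fit == pytest.approx(
            res.sem_empirical_sd, rel=0.1
        )

    def test_determinism_under_seed(self):
        data = np.random.default_rng(0).normal(size=30)
        r1 = bootstrap_mean(data, 1000, seed=9)
        r2 = bootstrap_mean(data, 1000, seed=9)
        assert np.array_equal(r1.resampled_means, r2.resampled_means)

    @pytest.mark.parametrize("n,rel_tol", [(30, 0.35), (100, 0.2), (300, 0.15)])
    def test_sem_converges_to_sigma_over_sqrt_n(self, n, rel_tol):
        rng = np.random.default_rng(n)
        data = rng.normal(0.0, 2.0, size=n)
        res = bootstrap_mean(data, 5000, seed=n)
        assert res.sem_gaussian_fit == pytest.approx(2.0 / np.sqrt(n), rel=rel_tol)

    def test_too_small_sample_raises(self):
        with pytest.raises(ValueError, match="at least 2"):
            bootstrap_mean([1.0], seed=0)


class TestZComparison:
    def test_identical_distributions_give_zero_z(self):
        data = np.random.default_rng(3).normal(size=50)
        res = bootstrap_mean(data, 2000, seed=1)
        z, p = bootstrap_z_comparison(res, res)
        assert z == 0.0 and p == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        """means 1 vs 0 with SEMs 0.5 each: z = 1/sqrt(0.5) ~ 1.414."""
        a = bootstrap_mean([0.0, 2.0], 100, seed=0)
        b = bootstrap_mean([0.0, 2.0], 100, seed=0)
        a.mean_of_means, a.sem_gaussian_fit = 1.0, 0.5
        b.mean_of_means, b.sem_gaussian_fit = 0.0, 0.5
        z, p = bootstrap_z_comparison(a, b)
        assert z == pytest.approx(np.sqrt(2.0))
        assert p == pytest.approx(2 * (1 - sps.norm.cdf(np.sqrt(2))), rel=1e-6)

    def test_swapping_groups_negates_z(self):
        rng = np.random.default_rng(8)
        ra = bootstrap_mean(rng.normal(1.0, 1.0, 60), 2000, seed=2)
        rb = bootstrap_mean(rng.normal(0.0, 1.0, 80), 2000, seed=3)
        z_ab, p_ab = bootstrap_z_comparison(ra, rb)
        z_ba, p_ba = bootstrap_z_comparison(rb, ra)
        assert z_ab == pytest.approx(-z_ba)
        assert p_ab == pytest.approx(p_ba)

    def test_zero_sems_raise(self):
        ra = bootstrap_mean([4.0, 4.0, 4.0], 100, seed=0)
        rb = bootstrap_mean([2.0, 2.0, 2.0], 100, seed=0)
        with pytest.raises(ValueError, match="zero"):
            bootstrap_z_comparison(ra, rb)

    def test_measured_z_recovers_configured_three_sem_effect(self):
        """A true 3-pooled-SEM group effect yields measured z centered on 3.

        The measured z of any single replicate scatters around the true
        effect with unit SD, so the *mean* over replicates is the
        recoverable quantity.
        """
        rng = np.random.default_rng(77)
        n_a, n_b, sigma = 60, 200, 1.0
        pooled_sem = sigma * np.sqrt(1 / n_a + 1 / n_b)
        zs = []
        for r in range(40):
            a = rng.normal(3.0 * pooled_sem, sigma, n_a)
            b = rng.normal(0.0, sigma, n_b)
            ra = bootstrap_mean(a, 2000, seed=2 * r)
            rb = bootstrap_mean(b, 2000, seed=2 * r + 1)
            zs.append(bootstrap_z_comparison(ra, rb)[0])
        assert np.mean(zs) == pytest.approx(3.0, abs=0.6)


def test_compare_groups_bundles_both_tests():
    rng = np.random.default_rng(5)
    cmp = compare_groups(
        rng.normal(1.0, 1.0, 6), rng.normal(0.0, 1.0, 10), "metric",
        n_resamples=2000, seed=4,
    )
    assert 0 < cmp.p_ranksum <= 1
    assert np.isfinite(cmp.z_score_bootstrap)


class TestDDCt:
    def _table(self):
        return pd.DataFrame(
            {
                "sample": ["s1", "s2", "s3", "s4"],
                "group": ["control", "control", "treated", "treated"],
                "gene": ["Pvalb"] * 4,
                "reference_gene": ["Gapdh"] * 4,
                "ct": [20.0, 21.0, 22.5, 23.5],
                "ct_ref": [15.0, 16.0, 15.0, 16.0],
            }
        )

    def test_control_mean_maps_to_fold_one(self):
        out = ddct_fold_change(self._table(), "control")
        control_folds = out.loc[out.group == "control", "fold_change"]
        # both control samples sit at the control-mean ΔCt of 5.0
        assert np.allclose(control_folds, 1.0)

    def test_hand_arithmetic(self):
        out = ddct_fold_change(self._table(), "control")
        treated = out.loc[out.group == "treated"]
        # ΔCt = 7.5 both; ΔΔCt = 2.5 -> fold 2^-2.5
        assert np.allclose(treated["fold_change"], 2.0**-2.5)
        assert np.allclose(
            treated["sqrt_fold_change"], np.sqrt(2.0**-2.5)
        )

    @pytest.mark.parametrize("ddct,fold,sqrt_fold", [(-1.0, 2.0, np.sqrt(2.0)), (2.0, 0.25, 0.5)])
    def test_fold_table(self, ddct, fold, sqrt_fold):
        df = pd.DataFrame(
            {
                "sample": ["c", "t"],
                "group": ["control", "treated"],
                "gene": ["g"] * 2,
                "reference_gene": ["r"] * 2,
                "ct": [10.0, 10.0 + ddct],
                "ct_ref": [5.0, 5.0],
            }
        )
        out = ddct_fold_change(df, "control")
        t = out.loc[out.group == "treated"].iloc[0]
        assert t["fold_change"] == pytest.approx(fold)
        assert t["sqrt_fold_change"] == pytest.approx(sqrt_fold)

    def test_translation_invariance(self):
        """Adding a constant to every Ct (target and reference) changes nothing."""
        base = ddct_fold_change(self._table(), "control")
        shifted_table = self._table()
        shifted_table["ct"] += 3.7
        shifted_table["ct_ref"] += 3.7
        shifted = ddct_fold_change(shifted_table, "control")
        assert np.allclose(base["fold_change"], shifted["fold_change"])

    def test_missing_reference_names_sample(self):
        df = self._table()
        df.loc[2, "ct_ref"] = np.nan
        with pytest.raises(ValueError, match="s3"):
            ddct_fold_change(df, "control")

    def test_missing_control_group_raises(self):
        with pytest.raises(ValueError, match="control"):
            ddct_fold_change(self._table(), "untreated")
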