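"""Group summaries and the comparison tests (rank, chi-square, correlation)."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from ctcenter import (
    CohortSpec,
    chi2_2x2,
    compare_groups,
    normality_check,
    pearson_r2,
    rank_test,
    sample_cohort,
    summarize,
)


class TestSummarize:
    def test_small_integer_vector(self):
        s = summarize([1, 2, 3, 4, 5])
        assert s.mean == 3.0
        assert s.median == 3.0
        assert (s.q1, s.q3) == (2.0, 4.0)

    def test_constant_vector_ci_collapses(self):
        s = summarize([4.25] * 10)
        assert s.sd == 0.0
        assert s.ci_low == s.ci_high == 4.25

    def test_normal_approximation_ci_reported_bias(self):
        """n=33, mean 7.2, SD 10.25 gives the 95% CI [3.7, 10.7]."""
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 33)
        x = (x - x.mean()) / x.std(ddof=1) * 10.25 + 7.2
        s = summarize(x)
        assert s.ci_low == pytest.approx(3.7, abs=0.05)
        assert s.ci_high == pytest.approx(10.7, abs=0.05)

    def test_n_below_two_rejected(self):
        with pytest.raises(ValueError):
            summarize([1.0])


def brute_force_ranksum_p(a, b):
    """Independent enumeration oracle: two-sided rank-sum p over all
    assignments of the pooled midranks to group A."""
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    n_a = len(a)
    expected = n_a * (len(pooled) + 1) / 2.0
    w_obs = ranks[:n_a].sum()
    devs = [
        abs(sum(combo) - expected)
        for combo in itertools.combinations(ranks, n_a)
    ]
    dev = abs(w_obs - expected)
    hits = sum(1 for v in devs if v >= dev - 1e-9)
    return hits / len(devs)


class TestRankTest:
    def test_identical_samples_p_one(self):
        _, p = rank_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == 1.0

    def test_fully_separated_small_groups(self):
        """{1,2,3} vs {4,5,6}: exact two-sided p = 2/20 = 0.1."""
        w, p = rank_test([1, 2, 3], [4, 5, 6])
        assert w == 6.0
        assert p == pytest.approx(0.1)

    def test_agrees_with_scipy_exact_on_tie_free_data(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            n_a, n_b = rng.integers(2, 7, size=2)
            a = rng.normal(0, 1, n_a)
            b = rng.normal(0.8, 1, n_b)
            _, p = rank_test(a, b)
            ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue
            assert p == pytest.approx(float(ref), abs=1e-12)

    def test_agrees_with_enumeration_including_ties(self):
        rng = np.random.default_rng(7)
        for _ in range(8):
            a = rng.integers(0, 4, size=int(rng.integers(2, 6))).astype(float)
            b = rng.integers(0, 4, size=int(rng.integers(2, 6))).astype(float)
            _, p = rank_test(a, b)
            assert p == pytest.approx(brute_force_ranksum_p(a, b), abs=1e-12)

    def test_shift_monotonically_decreases_p_to_exact_minimum(self):
        a = [1.0, 2.0, 3.0, 4.0]
        ps = [rank_test(a, [x + shift for x in a])[1] for shift in (0.0, 0.5, 2.0, 100.0)]
        assert all(p1 >= p2 for p1, p2 in zip(ps, ps[1:]))
        # full separation: 2 / C(8, 4)
        assert ps[-1] == pytest.approx(2.0 / 70.0)

    def test_asymptotic_branch_close_to_exact_near_boundary(self):
        rng = np.random.default_rng(11)
        a = rng.normal(0, 1, 10)
        b = rng.normal(0.5, 1, 10)
        _, p_exact = rank_test(a, b, method="exact")
        _, p_asym = rank_test(a, b, method="asymptotic")
        assert p_asym == pytest.approx(p_exact, abs=0.05)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            rank_test([], [1.0])


class TestChi2:
    def test_reported_offcentering_table(self):
        """4/34 vs 0/33 patients off-center by >20 mm: chi2≈4.13, p≈0.04."""
        chi2, p = chi2_2x2(4, 30, 0, 33)
        assert chi2 == pytest.approx(4.13, abs=0.01)
        assert round(p, 2) == 0.04

    def test_no_association(self):
        chi2, p = chi2_2x2(10, 10, 10, 10)
        assert chi2 == 0.0
        assert p == 1.0

    def test_closed_form_arithmetic(self):
        chi2, _ = chi2_2x2(2, 8, 8, 2)
        assert chi2 == pytest.approx(7.2)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            chi2_2x2(0, 5, 0, 5)

    def test_group_swap_invariance(self):
        assert chi2_2x2(4, 30, 0, 33) == chi2_2x2(0, 33, 4, 30)

    def test_matches_scipy_without_correction(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            a, b, c, d = rng.integers(1, 20, size=4)
            chi2, p = chi2_2x2(int(a), int(b), int(c), int(d))
            ref = sps.chi2_contingency([[a, b], [c, d]], correction=False)
            assert chi2 == pytest.approx(ref.statistic)
            assert p == pytest.approx(ref.pvalue)


class TestPearson:
    def test_perfect_linearity(self):
        x = np.arange(10.0)
        r, r2, _ = pearson_r2(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert r2 == pytest.approx(1.0)

    def test_independent_vectors_r2_near_zero(self):
        rng = np.random.default_rng(12)
        x, y = rng.normal(size=(2, 5000))
        _, r2, _ = pearson_r2(x, y)
        assert r2 < 0.01

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_r2([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_simulated_chest_pairs_match_reported_correlation(self):
        """With the default measurement-bias noise, ruler vs true chest
        thickness correlates near the clinically reported R^2 of 0.76."""
        spec = CohortSpec(n_patients=4000, seed=21)
        cohort = sample_cohort(spec)
        ruler = [p.ruler_chest_thickness for p in cohort]
        true = [p.true_chest_thickness for p in cohort]
        _, r2, p = pearson_r2(ruler, true)
        assert p < 0.01
        # analytic: r2 = sd_true^2 / (sd_true^2 + sd_bias^2) = 17^2/(17^2+10.25^2) ~ 0.73
        assert 0.65 < r2 < 0.82


class TestNormality:
    def test_normal_sample_not_rejected(self):
        rng = np.random.default_rng(2)
        assert normality_check(rng.normal(size=500)) > 0.05

    def test_skewed_sample_rejected(self):
        rng = np.random.default_rng(2)
        assert normality_check(rng.exponential(size=200)) < 0.05

    def test_constant_vector_error(self):
        with pytest.raises(ValueError):
            normality_check([1.0] * 10)


class TestCompareGroups:
    def test_two_group_table(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(
            {
                "group": ["a"] * 30 + ["b"] * 30,
                "metric": np.r_[rng.normal(0, 1, 30), rng.normal(2, 1, 30)],
            }
        )
        (comp,) = compare_groups(df, ["metric"])
        assert comp.p_value < 0.01
        assert comp.summary_a.n == comp.summary_b.n == 30

    def test_insufficient_n_reported_not_raised(self):
        df = pd.DataFrame({"group": ["a", "b"], "metric": [1.0, 2.0]})
        (comp,) = compare_groups(df, ["metric"])
        assert comp.test_name == "insufficient n"
        assert np.isnan(comp.p_value)
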