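import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as scipy_stats

from cqdiff import (
    bh_adjust,
    exhaustive_permutation_test,
    permutation_yuen_test,
    trimmed_mean,
    winsorized_variance,
    yuen_welch_statistic,
)


def yuen_reference(x, y, trim):
    """Independent straight-from-the-formula Yuen-Welch implementation
    (separate code path from the vectorized production routine)."""
    parts = []
    for a in (np.sort(np.asarray(x, float)), np.sort(np.asarray(y, float))):
        n = len(a)
        g = math.floor(trim * n)
        h = n - 2 * g
        tmean = np.mean(a[g:n - g])
        w = a.copy()
        w[:g] = a[g]
        w[n - g:] = a[n - g - 1]
        s2w = np.sum((w - np.mean(w)) ** 2) / (n - 1)
        parts.append((tmean, (n - 1) * s2w / (h * (h - 1))))
    (tx, dx), (ty, dy) = parts
    return (tx - ty) / math.sqrt(dx + dy)


class TestTrimmedMean:
    def test_ten_percent_trim_drops_one_per_tail(self):
        assert trimmed_mean(range(1, 11), 0.1) == pytest.approx(5.5)

    def test_constant_vector(self):
        for g in (0.0, 0.1, 0.25, 0.49):
            assert trimmed_mean([3.2] * 7, g) == pytest.approx(3.2)

    def test_zero_trim_is_arithmetic_mean(self):
        x = [1.5, 2.0, 9.0, -4.0]
        assert trimmed_mean(x, 0.0) == pytest.approx(np.mean(x))

    def test_agrees_with_scipy(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            x = rng.normal(size=rng.integers(3, 30))
            for g in (0.05, 0.1, 0.2):
                assert trimmed_mean(x, g) == pytest.approx(
                    scipy_stats.trim_mean(x, g), rel=1e-12
                )

    def test_overtrimming_is_error(self):
        with pytest.raises(ValueError):
            trimmed_mean([1.0, 2.0], 0.5)


class TestWinsorizedVariance:
    def test_hand_winsorized_example(self):
        # n=5, gamma=0.2 -> g=1; (1,2,3,4,10) winsorizes to (2,2,3,4,4), var=1
        assert winsorized_variance([1, 2, 3, 4, 10], 0.2) == pytest.approx(1.0)

    def test_constant_vector_is_zero(self):
        assert winsorized_variance([5.0] * 6, 0.1) == 0.0

    def test_zero_trim_is_sample_variance(self):
        x = np.array([0.3, -1.2, 2.2, 0.9, 1.1])
        assert winsorized_variance(x, 0.0) == pytest.approx(x.var(ddof=1))

    def test_too_few_retained_is_error(self):
        with pytest.raises(ValueError):
            winsorized_variance([1.0, 2.0, 3.0], 0.4)


class TestYuenWelchStatistic:
    def test_identical_groups_give_zero(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        assert yuen_welch_statistic(x, x, 0.1) == 0.0

    def test_zero_trim_reduces_to_welch(self):
        rng = np.random.default_rng(42)
        x, y = rng.normal(0, 1, 8), rng.normal(0.5, 2, 11)
        welch = scipy_stats.ttest_ind(x, y, equal_var=False).statistic
        assert yuen_welch_statistic(x, y, 0.0) == pytest.approx(welch, abs=1e-12)

    def test_matches_independent_reference_implementation(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            nx, ny = rng.integers(6, 25, 2)
            x, y = rng.normal(0, 1, nx), rng.normal(0.3, 1.7, ny)
            assert yuen_welch_statistic(x, y, 0.1) == pytest.approx(
                yuen_reference(x, y, 0.1), rel=1e-12
            )

    def test_degenerate_variance_with_unequal_means_is_error(self):
        with pytest.raises(ValueError, match="degenerate"):
            yuen_welch_statistic([1.0, 1.0, 1.0], [2.0, 2.0, 2.0], 0.0)

    def test_outlier_perturbs_trimmed_statistic_less_than_welch(self):
        """Robustness: a +10 SD outlier moves the 10%-trimmed statistic less
        than the untrimmed Welch statistic, over a seeded battery."""
        rng = np.random.default_rng(77)
        d_trim, d_welch = [], []
        for _ in range(40):
            x, y = rng.normal(0, 1, 12), rng.normal(0, 1, 12)
            x_out = np.append(x[:-1], 10.0)
            d_trim.append(abs(yuen_welch_statistic(x_out, y, 0.1) - yuen_welch_statistic(x, y, 0.1)))
            d_welch.append(abs(yuen_welch_statistic(x_out, y, 0.0) - yuen_welch_statistic(x, y, 0.0)))
        # the trimmed statistic resists the outlier in the aggregate and in
        # the large majority of instances
        assert np.mean(d_trim) < np.mean(d_welch)
        assert np.mean(np.array(d_trim) < np.array(d_welch)) >= 0.75


class TestPermutationTest:
    def test_constant_equal_groups_give_p_one(self):
        res = permutation_yuen_test([2.0] * 5, [2.0] * 5, 0.1, 200, 0)
        assert res.pvalue == 1.0 and res.statistic == 0.0

    def test_determinism_with_seed(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(0, 1, 10), rng.normal(1, 1, 10)
        r1 = permutation_yuen_test(x, y, 0.1, 500, 123)
        r2 = permutation_yuen_test(x, y, 0.1, 500, 123)
        assert r1.pvalue == r2.pvalue and r1.statistic == r2.statistic

    def test_pvalue_bounds(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(0, 1, 6), rng.normal(5, 1, 6)
        res = permutation_yuen_test(x, y, 0.1, 99, 7)
        assert 1 / 100 <= res.pvalue <= 1.0

    def test_monte_carlo_approximates_exhaustive(self):
        rng = np.random.default_rng(3)
        for _ in range(4):
            x, y = rng.normal(0, 1, 4), rng.normal(0.8, 1, 4)
            exact = exhaustive_permutation_test(x, y, 0.1).pvalue
            mc = permutation_yuen_test(x, y, 0.1, 20000, 11).pvalue
            assert abs(mc - exact) < 0.02


class TestExhaustiveTest:
    def test_two_vs_two_extremes(self):
        # only the two fully separated relabelings reach |T_obs|
        res = exhaustive_permutation_test([1.0, 2.0], [3.0, 4.0], 0.0)
        assert res.pvalue == pytest.approx(2 / 6)
        assert res.n_permutations == 6

    def test_identical_groups_give_p_one(self):
        res = exhaustive_permutation_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], 0.0)
        assert res.pvalue == 1.0

    def test_symmetric_in_group_order(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(0, 1, 4), rng.normal(1, 1, 5)
        assert (
            exhaustive_permutation_test(x, y, 0.1).pvalue
            == exhaustive_permutation_test(y, x, 0.1).pvalue
        )

    def test_combination_cap(self):
        x = np.arange(30.0)
        with pytest.raises(ValueError, match="exceeds cap"):
            exhaustive_permutation_test(x, x, 0.1, max_combinations=100)


def bh_reference(p):
    """Direct step-up definition: q_(i) = min_{j>=i} min(1, p_(j) * m / j)."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        running = min(running, p[order[rank - 1]] * m / rank)
        q[order[rank - 1]] = running
    return q


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_equal_ratio_ladder_collapses(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    @settings(max_examples=80, deadline=None, derandomize=True)
    def test_matches_step_up_definition(self, p):
        np.testing.assert_allclose(bh_adjust(p), bh_reference(p), atol=1e-12)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_adjusted_dominates_raw_and_caps_at_one(self, p):
        q = bh_adjust(p)
        assert (q >= np.asarray(p) - 1e-15).all() and (q <= 1.0).all()

    def test_missing_entries_excluded_from_family(self):
        q = bh_adjust([0.01, np.nan, 0.04])
        assert np.isnan(q[1])
        np.testing.assert_allclose(q[[0, 2]], bh_reference([0.01, 0.04]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.1, 1.2])
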