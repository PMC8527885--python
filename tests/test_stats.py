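"""Statistical machinery: odds ratios, exact and rank tests, BH, IRLS."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from biofilmquant.stats import (Contingency2x2, ConvergenceError, bh_adjust,
                                confusion_metrics, fisher_exact,
                                fit_grouped_logistic, kruskal_wallis,
                                log_t_test, mann_whitney_u, odds_ratio_2x2)

cells = st.integers(1, 50)


class TestOddsRatio:
    def test_screening_ibs_vs_healthy(self):
        # 65/114 IBS vs 10/155 healthy-control biofilm carriers
        r = odds_ratio_2x2(Contingency2x2(65, 49, 10, 145))
        assert round(r.odds_ratio, 1) == 19.2

    def test_symmetric_table_is_unity(self):
        r = odds_ratio_2x2(Contingency2x2(10, 10, 10, 10))
        assert r.odds_ratio == pytest.approx(1.0)
        assert r.ci_low < 1.0 < r.ci_high

    def test_simple_arithmetic(self):
        r = odds_ratio_2x2(Contingency2x2(10, 10, 5, 20))
        assert r.odds_ratio == pytest.approx(4.0)

    @given(cells, cells, cells, cells)
    def test_reciprocal_under_row_swap(self, a, b, c, d):
        r1 = odds_ratio_2x2(Contingency2x2(a, b, c, d))
        r2 = odds_ratio_2x2(Contingency2x2(c, d, a, b))
        assert r1.odds_ratio * r2.odds_ratio == pytest.approx(1.0)

    def test_zero_cell_triggers_continuity_correction(self):
        r = odds_ratio_2x2(Contingency2x2(5, 0, 3, 7))
        assert r.continuity_corrected
        assert np.isfinite(r.odds_ratio)

    def test_empty_margin_is_an_error(self):
        with pytest.raises(ValueError):
            odds_ratio_2x2(Contingency2x2(0, 0, 5, 5))


def fisher_enumeration(a, b, c, d):
    """Independent minlike oracle: enumerate all tables with fixed margins."""
    n, r1, c1 = a + b + c + d, a + b, a + c
    p_obs = sps.hypergeom.pmf(a, n, r1, c1)
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    total = 0.0
    for k in range(lo, hi + 1):
        pk = sps.hypergeom.pmf(k, n, r1, c1)
        if pk <= p_obs * (1 + 1e-7):
            total += pk
    return min(1.0, total)


class TestFisherExact:
    def test_balanced_table_p_is_one(self):
        assert fisher_exact(Contingency2x2(5, 5, 5, 5)).p_value == \
            pytest.approx(1.0)

    def test_diagonal_table_enumeration(self):
        # two extreme tables out of C(6,3)=20 arrangements, each 1/20
        assert fisher_exact(Contingency2x2(3, 0, 0, 3)).p_value == \
            pytest.approx(0.1)

    @given(st.integers(0, 8), st.integers(0, 8), st.integers(0, 8),
           st.integers(0, 8))
    def test_matches_full_enumeration_small_tables(self, a, b, c, d):
        if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
            return
        got = fisher_exact(Contingency2x2(a, b, c, d)).p_value
        assert got == pytest.approx(fisher_enumeration(a, b, c, d), rel=1e-6)

    @given(cells, cells, cells, cells)
    def test_invariant_under_transposition(self, a, b, c, d):
        p1 = fisher_exact(Contingency2x2(a, b, c, d)).p_value
        p2 = fisher_exact(Contingency2x2(a, c, b, d)).p_value
        assert p1 == pytest.approx(p2, rel=1e-9)

    def test_doubling_rule_exposed(self):
        r = fisher_exact(Contingency2x2(3, 0, 0, 3), rule="doubling")
        assert r.p_value == pytest.approx(0.1)
        assert "doubling" in r.method


class TestMannWhitney:
    def test_complete_separation(self):
        r = mann_whitney_u([1, 2], [3, 4])
        assert r.statistic == 0.0
        assert r.p_value == pytest.approx(2 / 6)
        assert "exact" in r.method

    def test_identical_samples(self):
        x = [1.0, 2.0, 3.0, 4.0]
        r = mann_whitney_u(x, x)
        assert r.statistic == pytest.approx(len(x) ** 2 / 2)
        assert r.p_value > 0.9

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])

    @given(st.lists(st.integers(0, 30), min_size=2, max_size=12),
           st.lists(st.integers(0, 30), min_size=2, max_size=12))
    def test_u_statistics_conserve(self, x, y):
        ux = mann_whitney_u(x, y).statistic
        uy = mann_whitney_u(y, x).statistic
        assert ux + uy == pytest.approx(len(x) * len(y))


class TestKruskalWallis:
    def test_two_groups_agree_with_mann_whitney(self):
        rng = np.random.default_rng(8)
        x, y = rng.normal(0, 1, 40), rng.normal(0.4, 1, 40)
        p_kw = kruskal_wallis(x, y).p_value
        p_mw = mann_whitney_u(x, y).p_value
        assert abs(p_kw - p_mw) < 0.02

    def test_identical_values_degenerate(self):
        r = kruskal_wallis([2.0, 2.0], [2.0, 2.0, 2.0])
        assert r.statistic == 0.0 and r.p_value == 1.0

    def test_type_one_error_rate_under_null(self):
        rng = np.random.default_rng(17)
        rejections = 0
        n_sim = 500
        for _ in range(n_sim):
            groups = [rng.uniform(size=50) for _ in range(3)]
            if kruskal_wallis(*groups).p_value <= 0.05:
                rejections += 1
        assert abs(rejections / n_sim - 0.05) <= 0.02


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03]) == pytest.approx([0.03])

    def test_stepup_arithmetic(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_equal_inputs_stay_equal(self):
        out = bh_adjust([0.2, 0.2, 0.2])
        assert np.all(out == out[0])

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1,
                    max_size=20))
    def test_matches_stepup_and_never_below_raw(self, p):
        adj = bh_adjust(p)
        assert np.all(adj >= np.asarray(p) - 1e-12)
        assert np.all(adj <= 1.0)
        # independent step-up oracle: running min of p_(k) * m / k
        arr = np.asarray(p)
        m = len(arr)
        order = np.argsort(arr, kind="stable")
        expect = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            running = min(running, arr[order[rank - 1]] * m / rank)
            expect[order[rank - 1]] = running
        np.testing.assert_allclose(adj, expect, atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestGroupedLogistic:
    def test_saturated_two_by_two_equals_crude_or(self):
        X = np.array([[1.0, 0.0], [1.0, 1.0]])
        fit = fit_grouped_logistic(X, [10, 65], [155, 114])
        crude = odds_ratio_2x2(Contingency2x2(65, 49, 10, 145)).odds_ratio
        assert fit.odds_ratios[1] == pytest.approx(crude, rel=1e-12)

    def test_center_adjusted_ibs_or_near_printed_value(self):
        # groups: (cohort, center) with successes/totals from the
        # screening table; exp(cohort coefficient) should stay near 19.2
        X = np.array([
            [1.0, 0.0, 0.0],  # healthy, Austria
            [1.0, 0.0, 1.0],  # healthy, Germany
            [1.0, 1.0, 0.0],  # IBS, Austria
            [1.0, 1.0, 1.0],  # IBS, Germany
        ])
        fit = fit_grouped_logistic(X, [8, 2, 52, 13], [112, 43, 86, 28])
        assert fit.odds_ratios[1] == pytest.approx(19.2, abs=0.5)

    def test_matches_statsmodels_glm(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(5)
        X = np.column_stack([np.ones(8), rng.normal(size=8),
                             rng.integers(0, 2, 8).astype(float)])
        beta = np.array([-0.5, 0.8, 0.3])
        n = rng.integers(30, 80, 8)
        p = sps.logistic.cdf(X @ beta)
        s = rng.binomial(n, p)
        fit = fit_grouped_logistic(X, s, n)
        glm = sm.GLM(np.column_stack([s, n - s]), X,
                     family=sm.families.Binomial()).fit()
        np.testing.assert_allclose(fit.coef, glm.params, rtol=1e-6)
        np.testing.assert_allclose(fit.se, glm.bse, rtol=1e-5)

    def test_recovers_planted_odds_ratio(self):
        # true OR 3.0 (p: 0.2 vs 0.4286), n = 5000 per replicate
        rng = np.random.default_rng(12)
        X = np.array([[1.0, 0.0], [1.0, 1.0]])
        p = np.array([0.2, 0.75 / 1.75])
        ests = []
        for _ in range(200):
            s = rng.binomial([2500, 2500], p)
            ests.append(fit_grouped_logistic(X, s, [2500, 2500])
                        .odds_ratios[1])
        se = np.std(ests, ddof=1) / np.sqrt(len(ests))
        assert abs(np.mean(ests) - 3.0) <= 3 * se

    def test_separation_raises_diagnostic(self):
        X = np.array([[1.0, 0.0], [1.0, 1.0]])
        with pytest.raises(ConvergenceError):
            fit_grouped_logistic(X, [0, 50], [50, 50])

    def test_rank_deficient_design_rejected(self):
        X = np.array([[1.0, 2.0], [1.0, 2.0], [1.0, 2.0]])
        with pytest.raises(ValueError):
            fit_grouped_logistic(X, [1, 2, 3], [10, 10, 10])


class TestConfusionMetrics:
    def test_perfect_agreement(self):
        assert confusion_metrics(10, 0, 0, 10)["accuracy"] == 1.0

    def test_screening_concordance_cells(self):
        m = confusion_metrics(33, 19, 4, 28)
        assert m["accuracy"] == pytest.approx(61 / 84)

    def test_zero_denominator_is_nan_not_error(self):
        m = confusion_metrics(0, 0, 3, 7)
        assert np.isnan(m["sensitivity"])
        assert m["specificity"] == 0.7


class TestLogTTest:
    def test_requires_positive_data(self):
        with pytest.raises(ValueError):
            log_t_test([1.0, -2.0], [1.0, 2.0])

    def test_scale_shift_on_log_scale(self):
        rng = np.random.default_rng(3)
        x = np.exp(rng.normal(0, 0.3, 40))
        r_same = log_t_test(x, x)
        assert r_same.p_value == pytest.approx(1.0)
        r_diff = log_t_test(x, x * 10)
        assert r_diff.p_value < 1e-6
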