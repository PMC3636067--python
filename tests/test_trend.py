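"""Trend filter: curvature penalty, solver optimality, CV, change/outlier calls."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from pdfluct import CohortSimSpec, TrendFilter, curvature_penalty, simulate_cohort
from pdfluct.trend import ols_line

from conftest import make_series
from oracles import curvature_by_loop, solve_trend_epigraph


def random_instance(rng, n=None, t_span=5.0):
    n = n if n is not None else int(rng.integers(5, 21))
    t = np.sort(rng.uniform(0, t_span, n))
    while np.any(np.diff(t) < 1e-3):
        t = np.sort(rng.uniform(0, t_span, n))
    y = rng.normal(20, 8, n)
    return t, y


class TestCurvaturePenalty:
    def test_linear_data_has_zero_curvature(self, rng):
        t = np.sort(rng.uniform(0, 10, 12))
        assert curvature_penalty(t, 3.0 + 2.5 * t) == pytest.approx(0.0, abs=1e-10)

    def test_hat_function_arithmetic(self):
        assert curvature_penalty([0, 1, 2], [0, 1, 0]) == pytest.approx(2.0)

    def test_matches_loop_oracle(self, rng):
        for _ in range(5):
            t, y = random_instance(rng, n=10)
            assert curvature_penalty(t, y) == pytest.approx(
                curvature_by_loop(t, y), rel=1e-12
            )

    def test_duplicate_times_rejected(self):
        with pytest.raises(ValueError):
            curvature_penalty([0, 1, 1, 2], [0, 1, 2, 3])


class TestFitTrend:
    def test_lam_zero_interpolates_data(self, rng):
        t, y = random_instance(rng)
        fit = TrendFilter(t, y).fit(0.0)
        np.testing.assert_allclose(fit.trend, y, atol=1e-12)

    def test_lam_above_max_gives_ols_line(self, rng):
        for _ in range(5):
            t, y = random_instance(rng)
            tf = TrendFilter(t, y)
            fit = tf.fit(tf.lam_max() * 1.000001)
            np.testing.assert_allclose(fit.trend, ols_line(t, y), atol=1e-6)

    def test_matches_convex_oracle(self, rng):
        """Penalized objective agrees with an independent epigraph-QP solve."""
        for _ in range(8):
            t, y = random_instance(rng)
            tf = TrendFilter(t, y)
            lam = float(rng.uniform(0.02, 1.5)) * max(tf.lam_max(), 0.1)
            fit = tf.fit(lam)
            _, obj_oracle = solve_trend_epigraph(t, y, lam)
            assert fit.objective == pytest.approx(obj_oracle, rel=1e-6, abs=1e-6)
            assert fit.duality_gap < 1e-6 * max(1.0, fit.objective)

    def test_regularization_monotonicity(self, rng):
        t, y = random_instance(rng, n=18)
        tf = TrendFilter(t, y)
        lams = np.geomspace(1e-3, 2, 12) * tf.lam_max()
        fits = [tf.fit(l) for l in lams]
        curv = np.array([f.curvature for f in fits])
        rss = np.array([f.rss for f in fits])
        assert np.all(np.diff(curv) <= 1e-7 * max(1, curv[0]))
        assert np.all(np.diff(rss) >= -1e-7 * max(1, rss[-1]))

    def test_fit_stays_within_data_range(self, rng):
        for _ in range(5):
            t, y = random_instance(rng)
            tf = TrendFilter(t, y)
            fit = tf.fit(0.3 * tf.lam_max())
            assert fit.trend.min() >= y.min() - 1e-8
            assert fit.trend.max() <= y.max() + 1e-8

    @given(shift=st.floats(-30, 30, allow_nan=False))
    def test_shift_equivariance(self, shift):
        t = np.array([0.0, 0.4, 1.1, 1.7, 2.5, 3.0, 4.2, 5.0])
        y = np.array([12.0, 15.0, 11.0, 18.0, 14.0, 19.0, 16.0, 22.0])
        base = TrendFilter(t, y).fit(0.5).trend
        shifted = TrendFilter(t, y + shift).fit(0.5).trend
        np.testing.assert_allclose(shifted, base + shift, atol=1e-6)

    @given(scale=st.floats(0.1, 10, allow_nan=False))
    def test_scale_equivariance(self, scale):
        t = np.array([0.0, 0.4, 1.1, 1.7, 2.5, 3.0, 4.2, 5.0])
        y = np.array([12.0, 15.0, 11.0, 18.0, 14.0, 19.0, 16.0, 22.0])
        base = TrendFilter(t, y).fit(0.5).trend
        scaled = TrendFilter(t, scale * y).fit(scale * 0.5).trend
        np.testing.assert_allclose(scaled, scale * base, atol=1e-5 * max(1, scale))

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            TrendFilter([0, 1], [1, 2])

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            TrendFilter([0, 1, 2], [1, np.nan, 2])

    def test_deterministic(self, rng):
        t, y = random_instance(rng)
        f1 = TrendFilter(t, y).fit(0.7)
        f2 = TrendFilter(t, y).fit(0.7)
        np.testing.assert_array_equal(f1.trend, f2.trend)


class TestCrossValidation:
    def test_near_linear_data_selects_heavy_smoothing(self, rng):
        t = np.sort(rng.uniform(0, 5, 30))
        y = 10 + 2 * t + rng.normal(0, 0.01, 30)
        fit = TrendFilter(t, y).fit_cv(seed=1)
        grid = fit.cv.lambdas
        assert fit.cv.lam_star >= np.median(grid)
        assert fit.curvature < 0.1

    def test_reproducible_from_seed(self, rng):
        t, y = random_instance(rng, n=25)
        f1 = TrendFilter(t, y).fit_cv(seed=9)
        f2 = TrendFilter(t, y).fit_cv(seed=9)
        np.testing.assert_array_equal(f1.cv.mean_test_error, f2.cv.mean_test_error)
        assert f1.cv.lam_star == f2.cv.lam_star
        np.testing.assert_array_equal(f1.trend, f2.trend)

    def test_grid_increasing_and_lam_star_attains_minimum(self, rng):
        t, y = random_instance(rng, n=25)
        fit = TrendFilter(t, y).fit_cv(seed=2)
        cv = fit.cv
        assert np.all(np.diff(cv.lambdas) > 0)
        assert cv.lam_star == cv.lambdas[np.argmin(cv.mean_test_error)]

    def test_slope_break_recovered_near_truth(self, rng):
        # piecewise-linear truth with one large break, small noise
        t = np.sort(rng.uniform(0, 6, 40))
        tc = 3.0
        y = 10 + 1.0 * np.minimum(t, tc) + 6.0 * np.maximum(t - tc, 0)
        y = y + rng.normal(0, 0.3, 40)
        fit = TrendFilter(t, y).fit_cv(seed=4)
        assert len(fit.knots) >= 1
        # at least one knot within one report spacing of the true break
        best = min(abs(t[k] - tc) for k in fit.knots)
        spacing = np.diff(t).max()
        assert best <= spacing + 1e-9

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            TrendFilter([0, 1, 2, 3], [1.0, 2.0, 1.0, 2.0]).fit_cv()


class TestChangeAndOutlierDetection:
    def test_ols_fit_has_no_abrupt_changes(self, rng):
        t, y = random_instance(rng)
        tf = TrendFilter(t, y)
        fit = tf.fit(tf.lam_max() * 2)
        assert fit.abrupt_changes(slope_jump_threshold=0.5) == []

    def test_infinite_threshold_empty(self, rng):
        t, y = random_instance(rng)
        fit = TrendFilter(t, y).fit(0.01)
        assert fit.abrupt_changes(slope_jump_threshold=np.inf) == []

    def test_injected_spike_flagged_exactly(self):
        cohort, _ = simulate_cohort(
            CohortSimSpec(
                n_patients=1, zero_noise=True, seed=3,
                archetype_weights={"smooth_increase": 1.0},
            )
        )
        s = cohort[0]
        scores = s.scores.astype(float).copy()
        scores[7] += 15
        fit = TrendFilter(s.times, scores).fit_cv(seed=0)
        flagged = fit.outlier_reports(k=3)
        assert 7 in flagged
        assert len(flagged) <= 2  # rounding noise must not flood the call

    def test_equal_magnitude_residuals_not_flagged(self):
        t = np.arange(8, dtype=float)
        fit = TrendFilter(t, np.zeros(8)).fit(0.0)
        object.__setattr__(fit, "trend", fit.trend + np.resize([1.0, -1.0], 8))
        assert len(fit.outlier_reports(k=3)) == 0

    def test_k_zero_flags_all_nonzero(self, rng):
        t, y = random_instance(rng, n=12)
        tf = TrendFilter(t, y)
        fit = tf.fit(tf.lam_max() * 2)
        r = np.abs(fit.residuals)
        np.testing.assert_array_equal(fit.outlier_reports(k=0), np.flatnonzero(r > 0))
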