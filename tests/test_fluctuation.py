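"""Gamma fluctuation GLM, bootstrap skewness test, CID scaling."""

import numpy as np
import pandas as pd
import pytest

from pdfluct import (
    CohortSimSpec,
    FluctuationModel,
    TrendFilter,
    bootstrap_skewness_test,
    compute_residuals,
    pool_residuals,
    scale_cid,
    simulate_cohort,
)
from pdfluct.simulate import _gamma_mad

from conftest import make_series


def records_from(t, abs_r, r=None):
    r = abs_r if r is None else r
    return pd.DataFrame({"t": t, "r": r, "abs_r": abs_r})


def simulate_records(rng, n, beta0, beta1, shape=2.0, t_lo=0.7, t_hi=6.0):
    """Records drawn directly from the generator's skewed residual law."""
    t = rng.uniform(t_lo, t_hi, n)
    scale = np.exp(beta0 + beta1 * t) / _gamma_mad(shape)
    r = scale * (rng.gamma(shape, 1.0, n) - shape)
    return records_from(t, np.abs(r), r)


class TestComputeResiduals:
    def test_lam_zero_gives_zero_residuals(self, rng):
        t = np.sort(rng.uniform(0, 4, 10))
        s = make_series(t, rng.integers(5, 30, 10))
        fit = TrendFilter.from_series(s).fit(0.0)
        rec = compute_residuals(s, fit)
        np.testing.assert_allclose(rec["r"], 0.0, atol=1e-10)

    def test_residuals_are_data_minus_trend(self, rng):
        t = np.sort(rng.uniform(0, 4, 12))
        s = make_series(t, rng.integers(5, 30, 12))
        fit = TrendFilter.from_series(s).fit(1.0)
        rec = compute_residuals(s, fit)
        np.testing.assert_allclose(rec["r"], s.scores - fit.trend)
        np.testing.assert_array_equal(rec["abs_r"], np.abs(rec["r"]))
        np.testing.assert_array_equal(rec["t"], t)

    def test_mismatched_fit_rejected(self, rng):
        t = np.sort(rng.uniform(0, 4, 10))
        s1 = make_series(t, rng.integers(5, 30, 10), pid="A")
        s2 = make_series(t + 0.5, rng.integers(5, 30, 10), pid="B")
        fit = TrendFilter.from_series(s1).fit(0.5)
        with pytest.raises(ValueError, match="correspond"):
            compute_residuals(s2, fit)

    def test_recovers_true_residuals_up_to_trend_error(self, small_cohort):
        cohort, truth = small_cohort
        frames, true_r = [], []
        for s in cohort:
            fit = TrendFilter.from_series(s).fit_cv(seed=1)
            frames.append(compute_residuals(s, fit))
            true_r.append(np.array(truth.patients[s.patient_id]["residuals"]))
        est = pool_residuals(frames)["r"].to_numpy()
        true_r = np.concatenate(true_r)
        rms = np.sqrt(np.mean((est - true_r) ** 2))
        # trend-estimation + rounding error stays well below the noise scale
        assert rms < 0.5 * np.sqrt(np.mean(true_r**2))


class TestGammaGLM:
    def test_noiseless_exponential_recovered_exactly(self):
        t = np.arange(10.0)
        rec = records_from(t, np.exp(0.5 + 0.1 * t))
        fit = FluctuationModel(rec).fit()
        assert fit.beta0 == pytest.approx(0.5, abs=1e-8)
        assert fit.beta1 == pytest.approx(0.1, abs=1e-8)

    def test_constant_response_gives_flat_fit(self):
        t = np.linspace(0, 8, 20)
        fit = FluctuationModel(records_from(t, np.full(20, 3.7))).fit()
        assert fit.beta1 == pytest.approx(0.0, abs=1e-10)
        assert fit.beta0 == pytest.approx(np.log(3.7), abs=1e-10)

    def test_score_equations_satisfied_at_optimum(self, rng):
        rec = simulate_records(rng, 800, 0.9555, 0.0512)
        model = FluctuationModel(rec)
        fit = model.fit()
        mu = np.exp(fit.beta0 + fit.beta1 * model.t)
        w = model.abs_r / mu - 1
        score0 = np.sum(w)
        score1 = np.sum(w * model.t)
        assert abs(score0) < 1e-8 * len(model.t)
        assert abs(score1) < 1e-8 * len(model.t) * max(1, model.t.max())

    def test_monte_carlo_recovery_and_coverage(self, rng):
        """Estimates land near truth and Wald CIs cover at ~95%."""
        beta = (0.9555, 0.0512)
        hits0 = hits1 = 0
        reps = 200
        est = []
        for _ in range(reps):
            fit = FluctuationModel(simulate_records(rng, 1000, *beta)).fit()
            se = fit.bse()
            hits0 += abs(fit.beta0 - beta[0]) < 1.96 * se[0]
            hits1 += abs(fit.beta1 - beta[1]) < 1.96 * se[1]
            est.append([fit.beta0, fit.beta1])
        est = np.asarray(est)
        for j in range(2):
            mc_se = est[:, j].std(ddof=1) / np.sqrt(reps)
            assert abs(est[:, j].mean() - beta[j]) < 3 * mc_se
        assert 0.91 <= hits0 / reps <= 0.98
        assert 0.91 <= hits1 / reps <= 0.98

    def test_wald_power_at_calibrated_effect(self, rng):
        """beta1 = 0.0512 is detected in >= 80% of default-size cohorts."""
        rejections = 0
        for _ in range(100):
            rec = simulate_records(rng, 2900, 0.9555, 0.0512)
            _, p = FluctuationModel(rec).fit().wald_beta1()
            rejections += p < 0.05
        assert rejections >= 80

    def test_zero_residuals_dropped_and_counted(self, rng):
        t = np.linspace(0, 5, 40)
        abs_r = np.exp(0.3 * t)
        abs_r[:5] = 0.0
        fit = FluctuationModel(records_from(t, abs_r)).fit()
        assert fit.n_dropped_zero == 5
        assert fit.n_used == 35

    def test_insufficient_data_rejected(self):
        with pytest.raises(ValueError):
            FluctuationModel(records_from([1.0] * 12, [2.0] * 12))  # one t value
        with pytest.raises(ValueError):
            FluctuationModel(records_from([1.0, 2.0], [0.5, 0.6]))  # too few


class TestPredict:
    def test_t0_is_exp_beta0_and_ci_log_symmetric(self, rng):
        fit = FluctuationModel(simulate_records(rng, 500, 1.0, 0.05)).fit()
        mean, lo, hi = fit.predict(0.0)
        assert mean == pytest.approx(np.exp(fit.beta0), rel=1e-12)
        assert np.log(mean) - np.log(lo) == pytest.approx(
            np.log(hi) - np.log(mean), rel=1e-9
        )

    def test_zero_covariance_degenerate_ci(self, rng):
        fit = FluctuationModel(simulate_records(rng, 500, 1.0, 0.05)).fit()
        fit.cov_params = np.zeros((2, 2))
        mean, lo, hi = fit.predict(3.0)
        assert lo == pytest.approx(mean) and hi == pytest.approx(mean)

    def test_strictly_increasing_iff_positive_slope(self, rng):
        fit = FluctuationModel(simulate_records(rng, 2000, 0.9555, 0.0512)).fit()
        t = np.linspace(0, 16, 50)
        mean, _, _ = fit.predict(t)
        assert fit.beta1 > 0
        assert np.all(np.diff(mean) > 0)


class TestBootstrapSkewness:
    def test_skewed_generator_law_detected(self, rng):
        rec = simulate_records(rng, 2000, 0.9555, 0.0512)
        res = bootstrap_skewness_test(rec["r"].to_numpy(), B=1000, seed=1)
        assert res.observed_skewness > 0
        assert res.p_value < 0.001

    def test_symmetric_law_usually_not_rejected(self, rng):
        """A symmetric residual law yields p > .05 in >= 90% of runs."""
        keep = 0
        runs = 40
        for i in range(runs):
            r = rng.normal(0, 2, 2000)
            res = bootstrap_skewness_test(r, B=300, seed=i)
            keep += res.p_value > 0.05
        assert keep >= 0.9 * runs

    def test_reproducible_from_seed(self, rng):
        r = rng.normal(0, 1, 100)
        a = bootstrap_skewness_test(r, B=200, seed=5)
        b = bootstrap_skewness_test(r, B=200, seed=5)
        assert a.t_statistic == b.t_statistic and a.p_value == b.p_value

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_skewness_test(np.zeros(100))
        with pytest.raises(ValueError):
            bootstrap_skewness_test(np.arange(5))


class TestScaleCID:
    @pytest.mark.parametrize(
        "total, expected",
        [(4.3, 1.7), (8.5, 3.3), (176.0, 68.0)],
    )
    def test_subscale_rescaling(self, total, expected):
        assert scale_cid(total) == expected

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            scale_cid(0.0)
        with pytest.raises(ValueError):
            scale_cid(-4.3)
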