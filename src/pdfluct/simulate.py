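"""Synthetic longitudinal and cross-sectional UPDRS cohort generators.

The longitudinal generator emulates a self-report cohort: ~100 patients,
a truncated-normal number of reports each (mean 29, SD 14, at least 15),
truncated-normal reporting gaps (mean 45, SD 12 days), first report
about one year after diagnosis, and ages at diagnosis of 54 (SD 9)
years.  Each patient's underlying trend is drawn from one of four
archetypes — two conforming to the textbook picture of smooth gradual
progression, two nonconforming (an abrupt slope change, or isolated
outlier reports on an otherwise smooth course).

Short-term fluctuation residuals are zero-mean and positively skewed:
r = s(t) * (G - k) with G ~ Gamma(shape k, scale 1), where the scale
s(t) is set so that E|r| = exp(beta0 + beta1 * t) exactly, using the
closed form E|G - k| = 2 k^k e^{-k} / Gamma(k).  Observed scores are the
trend plus residual (plus any injected spikes), clipped to [0, 68] and
rounded to the nearest integer, since UPDRS totals are ordinal.

Truncated normals are moment-calibrated: the underlying mean is shifted
(by root finding on the truncated-normal mean) so the *delivered*
truncated distribution has the requested mean, then sampled by
rejection, avoiding point masses that clamping would create.

The cross-sectional generator emulates a clinical reference sample:
one score per subject, labeled by on/off treatment state, with ages at
diagnosis of 59 (SD 10) years.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats

from .cohort import SCORE_MAX, SCORE_MIN, SymptomSeries

__all__ = [
    "CohortSimSpec",
    "CrossSectionSpec",
    "GroundTruth",
    "ARCHETYPES",
    "archetype_trend",
    "simulate_cohort",
    "simulate_cross_section",
    "write_ground_truth_json",
]

ARCHETYPES = ("smooth_increase", "plateau_decrease", "abrupt_change", "outlier_spikes")


def _check_positive(name, value):
    if not (value > 0):
        raise ValueError(f"{name} must be strictly positive, got {value}")


@dataclass
class CohortSimSpec:
    """Parameterization of the longitudinal cohort generator.

    ``beta0`` (log points) and ``beta1`` (per year) set the residual
    magnitude law E|r| = exp(beta0 + beta1 * t); the defaults are
    calibrated so mean absolute fluctuation is 2.6 points at diagnosis
    and 5.9 points 16 years later.  ``noise_shape`` is the gamma shape k
    of the skewed residual law (skewness 2/sqrt(k) > 0).
    """

    n_patients: int = 100
    age_mean_years: float = 54.0
    age_sd_years: float = 9.0
    reports_mean: float = 29.0
    reports_sd: float = 14.0
    reports_min: int = 15
    interval_mean_days: float = 45.0
    interval_sd_days: float = 12.0
    first_report_offset_years: float = 1.0
    first_report_jitter_years: float = 0.3
    beta0: float = 0.9555
    beta1: float = 0.0512
    noise_shape: float = 2.0
    zero_noise: bool = False
    archetype_weights: dict = field(
        default_factory=lambda: {
            "smooth_increase": 0.55,
            "plateau_decrease": 0.2,
            "abrupt_change": 0.15,
            "outlier_spikes": 0.1,
        }
    )
    label_probs: tuple = (0.6, 0.1, 0.3)  # on, off, unknown
    score_floor: int = SCORE_MIN
    score_ceiling: int = SCORE_MAX
    seed: int | None = None

    def __post_init__(self):
        if self.n_patients < 1:
            raise ValueError(f"n_patients must be >= 1, got {self.n_patients}")
        for name in ("age_sd_years", "reports_sd", "interval_sd_days",
                     "interval_mean_days", "noise_shape"):
            _check_positive(name, getattr(self, name))
        if self.reports_min < 2:
            raise ValueError(f"reports_min must be >= 2, got {self.reports_min}")
        if set(self.archetype_weights) - set(ARCHETYPES):
            raise ValueError(
                "archetype_weights has unknown archetypes "
                f"{sorted(set(self.archetype_weights) - set(ARCHETYPES))}"
            )
        w = np.array([self.archetype_weights.get(a, 0.0) for a in ARCHETYPES])
        if np.any(w < 0) or w.sum() <= 0:
            raise ValueError("archetype_weights must be nonnegative and normalizable")
        if len(self.label_probs) != 3 or not math.isclose(sum(self.label_probs), 1.0):
            raise ValueError("label_probs must be 3 probabilities summing to 1")


@dataclass
class CrossSectionSpec:
    """Parameterization of the cross-sectional reference generator."""

    n_subjects: int = 564
    age_mean_years: float = 59.0
    age_sd_years: float = 10.0
    on_score_mean: float = 16.0
    on_score_sd: float = 9.0
    off_score_mean: float = 24.0
    off_score_sd: float = 10.0
    p_off: float = 0.18
    seed: int | None = None

    def __post_init__(self):
        if self.n_subjects < 2:
            raise ValueError(f"n_subjects must be >= 2, got {self.n_subjects}")
        for name in ("on_score_sd", "off_score_sd"):
            _check_positive(name, getattr(self, name))
        if self.age_sd_years < 0:
            raise ValueError("age_sd_years must be >= 0")
        if not (0 <= self.p_off <= 1):
            raise ValueError("p_off must be in [0, 1]")


@dataclass
class GroundTruth:
    """Generative truth for one simulated cohort, for recovery testing."""

    beta0: float
    beta1: float
    noise_shape: float
    patients: dict = field(default_factory=dict)
    # patients[pid] = {archetype, params, true_trend, residuals,
    #                  spike_indices, spike_magnitudes, age_at_diagnosis}

    def to_dict(self) -> dict:
        return asdict(self)


def write_ground_truth_json(truth: GroundTruth, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth.to_dict(), fh, indent=1)


# -- archetype trends -----------------------------------------------------

def archetype_trend(name: str, params: dict, times) -> np.ndarray:
    """Evaluate a ground-truth trend archetype at the given times.

    ``smooth_increase``: concave saturating rise
        f(t) = intercept + amplitude * (1 - exp(-rate * t))
    ``plateau_decrease``: exponential decay to a plateau
        f(t) = plateau + (start - plateau) * exp(-rate * t)
    ``abrupt_change``: continuous piecewise-linear, one slope jump
        f(t) = intercept + slope1 * min(t, t_change)
                         + slope2 * max(t - t_change, 0)
    ``outlier_spikes``: the smooth_increase form; spikes are additive
        observation events recorded in the ground truth, not trend.
    """
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or (len(t) > 1 and np.any(np.diff(t) <= 0)):
        raise ValueError("times must be 1-d and strictly increasing")
    if name in ("smooth_increase", "outlier_spikes"):
        return params["intercept"] + params["amplitude"] * (
            1.0 - np.exp(-params["rate"] * t)
        )
    if name == "plateau_decrease":
        return params["plateau"] + (params["start"] - params["plateau"]) * np.exp(
            -params["rate"] * t
        )
    if name == "abrupt_change":
        tc = params["t_change"]
        return (
            params["intercept"]
            + params["slope1"] * np.minimum(t, tc)
            + params["slope2"] * np.maximum(t - tc, 0.0)
        )
    raise ValueError(f"unknown archetype {name!r}")


def _draw_archetype_params(name: str, rng: np.random.Generator, t_last: float) -> dict:
    # parameter ranges keep trends within roughly [5, 55] so that
    # clipping at the scale bounds stays rare
    if name in ("smooth_increase", "outlier_spikes"):
        return {
            "intercept": float(rng.uniform(8, 25)),
            "amplitude": float(rng.uniform(5, 25)),
            "rate": float(rng.uniform(0.1, 0.6)),
        }
    if name == "plateau_decrease":
        start = float(rng.uniform(20, 40))
        return {
            "start": start,
            "plateau": float(rng.uniform(8, start - 5)),
            "rate": float(rng.uniform(0.3, 1.0)),
        }
    if name == "abrupt_change":
        return {
            "intercept": float(rng.uniform(8, 20)),
            "slope1": float(rng.uniform(0.5, 2.0)),
            "slope2": float(rng.uniform(4.5, 10.0)),
            "t_change": float(rng.uniform(0.35 * t_last, 0.75 * t_last)),
        }
    raise ValueError(f"unknown archetype {name!r}")


# -- truncated-normal helpers ---------------------------------------------

def _calibrated_truncnorm(
    rng: np.random.Generator, target_mean: float, sd: float, lower: float, size: int
) -> np.ndarray:
    """Sample a lower-truncated normal whose delivered mean equals target.

    The pre-truncation location is found by root finding; draws then use
    rejection (scipy truncnorm), so there is no point mass at the bound.
    """
    if target_mean <= lower:
        raise ValueError(f"target mean {target_mean} must exceed lower bound {lower}")

    def trunc_mean(mu):
        a = (lower - mu) / sd
        return scipy.stats.truncnorm.mean(a, np.inf, loc=mu, scale=sd) - target_mean

    # if truncation is negligible the raw mean already works
    if (lower - target_mean) / sd < -8:
        mu = target_mean
    else:
        lo = target_mean - 10 * sd
        mu = scipy.optimize.brentq(trunc_mean, lo, target_mean + sd)
    a = (lower - mu) / sd
    return scipy.stats.truncnorm.rvs(
        a, np.inf, loc=mu, scale=sd, size=size, random_state=rng
    )


def _gamma_mad(shape: float) -> float:
    """E|G - k| for G ~ Gamma(k, 1): 2 k^k e^{-k} / Gamma(k)."""
    return 2.0 * math.exp(shape * math.log(shape) - shape - math.lgamma(shape))


# -- generators -----------------------------------------------------------

def simulate_cohort(spec: CohortSimSpec) -> tuple[list, GroundTruth]:
    """Generate a synthetic longitudinal cohort with its ground truth."""
    rng = np.random.default_rng(spec.seed)
    truth = GroundTruth(
        beta0=spec.beta0, beta1=spec.beta1, noise_shape=spec.noise_shape
    )
    weights = np.array([spec.archetype_weights.get(a, 0.0) for a in ARCHETYPES])
    weights = weights / weights.sum()
    mad = _gamma_mad(spec.noise_shape)

    n_reports = np.rint(
        _calibrated_truncnorm(
            rng, spec.reports_mean, spec.reports_sd,
            spec.reports_min - 0.5, spec.n_patients,
        )
    ).astype(int)
    n_reports = np.maximum(n_reports, spec.reports_min)

    cohort = []
    width = len(str(spec.n_patients))
    for i in range(spec.n_patients):
        pid = f"P{i + 1:0{width}d}"
        n = int(n_reports[i])
        gaps_days = _calibrated_truncnorm(
            rng, spec.interval_mean_days, spec.interval_sd_days, 0.0, n - 1
        )
        t0 = spec.first_report_offset_years + rng.uniform(
            -spec.first_report_jitter_years, spec.first_report_jitter_years
        )
        t0 = max(t0, 0.0)
        times = t0 + np.concatenate([[0.0], np.cumsum(gaps_days) / 365.25])

        archetype = str(rng.choice(ARCHETYPES, p=weights))
        params = _draw_archetype_params(archetype, rng, float(times[-1]))
        trend = archetype_trend(archetype, params, times)

        if spec.zero_noise:
            residuals = np.zeros(n)
        else:
            scale = np.exp(spec.beta0 + spec.beta1 * times) / mad
            g = rng.gamma(spec.noise_shape, 1.0, size=n)
            residuals = scale * (g - spec.noise_shape)

        spike_idx: list[int] = []
        spike_mag: list[float] = []
        signal = trend + residuals
        if archetype == "outlier_spikes":
            n_spikes = int(rng.integers(1, 4))
            spike_idx = sorted(
                int(j) for j in rng.choice(n, size=min(n_spikes, n), replace=False)
            )
            spike_mag = [float(rng.uniform(8, 18)) for _ in spike_idx]
            signal = signal.copy()
            for j, m in zip(spike_idx, spike_mag):
                signal[j] += m

        scores = np.rint(
            np.clip(signal, spec.score_floor, spec.score_ceiling)
        ).astype(int)
        labels = rng.choice(["on", "off", "unknown"], size=n, p=list(spec.label_probs))
        age = float(rng.normal(spec.age_mean_years, spec.age_sd_years))

        cohort.append(
            SymptomSeries(
                patient_id=pid,
                times=times,
                scores=scores,
                labels=labels,
                age_at_diagnosis=age,
            )
        )
        truth.patients[pid] = {
            "archetype": archetype,
            "params": params,
            "true_trend": trend.tolist(),
            "residuals": residuals.tolist(),
            "spike_indices": spike_idx,
            "spike_magnitudes": spike_mag,
            "age_at_diagnosis": age,
        }
    return cohort, truth


def simulate_cross_section(spec: CrossSectionSpec) -> pd.DataFrame:
    """Generate a cross-sectional reference sample (one score per subject).

    Returns a frame with columns ``subject_id, age_at_diagnosis,
    updrs_1_2, state``; scores are integers in [0, 68].
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    ages = rng.normal(spec.age_mean_years, spec.age_sd_years, size=n)
    off = rng.random(n) < spec.p_off
    mean = np.where(off, spec.off_score_mean, spec.on_score_mean)
    sd = np.where(off, spec.off_score_sd, spec.on_score_sd)
    scores = np.rint(
        np.clip(rng.normal(mean, sd), SCORE_MIN, SCORE_MAX)
    ).astype(int)
    width = len(str(n))
    return pd.DataFrame(
        {
            "subject_id": [f"S{i + 1:0{width}d}" for i in range(n)],
            "age_at_diagnosis": ages,
            "updrs_1_2": scores,
            "state": np.where(off, "off", "on"),
        }
    )
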