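"""End-to-end pipeline: simulate -> filter -> validate -> trend -> fluctuation.

One :class:`RunConfig` plus a master seed fully determines a run.  The
master seed is fanned out to the independent random stages (cohort
simulation, cross-section simulation, per-patient CV fold assignment,
bootstrap) through ``numpy.random.SeedSequence.spawn``, so the streams
are independent and adding a stage does not perturb earlier ones.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import (
    SymptomSeries,
    apply_inclusion_filter,
    read_cohort_csv,
    write_cohort_csv,
    write_cross_section_csv,
)
from .fluctuation import (
    FluctuationModel,
    bootstrap_skewness_test,
    compute_residuals,
    pool_residuals,
    scale_cid,
)
from .simulate import (
    CohortSimSpec,
    CrossSectionSpec,
    simulate_cohort,
    simulate_cross_section,
    write_ground_truth_json,
)
from .trend import TrendFilter
from .validation import ks_two_sample

logger = logging.getLogger("pdfluct")

__all__ = ["RunConfig", "RunReport", "run_pipeline", "PipelineError"]

#: CID thresholds on the total UPDRS (points), rescaled in the report.
MINIMAL_TOTAL_CID = 4.3
MODERATE_TOTAL_CID = 8.5


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Full parameterization of one pipeline run."""

    seed: int = 0
    cohort_csv: str | None = None  # if set, read instead of simulating
    sim: dict = field(default_factory=dict)  # CohortSimSpec overrides
    cross_section: dict = field(default_factory=dict)  # CrossSectionSpec overrides
    min_reports: int = 15
    max_mean_interval_days: float = 65.0
    n_lambdas: int = 30
    n_folds: int = 5
    bootstrap_B: int = 1000
    slope_jump_threshold: float = 4.0  # points/year, abrupt-change calls
    outlier_k: float = 3.0
    #: inflate each patient's residuals by sqrt(n/(n-df)), df = knots+2,
    #: before pooling for the GLM; corrects the downward bias from noise
    #: absorbed by the fitted trend (the n-p denominator idea)
    df_correction: bool = True
    out_dir: str | None = None

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


@dataclass
class RunReport:
    """Machine-readable result of one pipeline run."""

    config: dict
    version: str
    cohort: dict
    filter: dict
    validation: dict
    trends: dict
    fluctuation: dict
    skewness: dict
    cid: dict

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "config": self.config,
            "cohort": self.cohort,
            "filter": self.filter,
            "validation": self.validation,
            "trends": self.trends,
            "fluctuation": self.fluctuation,
            "skewness": self.skewness,
            "cid": self.cid,
        }

    def to_json(self) -> str:
        """Canonical JSON (sorted keys, no timestamps)."""
        return json.dumps(self.to_dict(), sort_keys=True, indent=1)


def _derive_seeds(master: int, n: int) -> list[int]:
    """Counter-based fan-out of the master seed into independent streams."""
    children = np.random.SeedSequence(master).spawn(n)
    return [int(c.generate_state(1)[0] % (2**31)) for c in children]


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute all stages; write artifacts if ``config.out_dir`` is set."""
    (seed_sim, seed_xs, seed_cv, seed_boot) = _derive_seeds(config.seed, 4)
    out = Path(config.out_dir) if config.out_dir else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    # -- stage: cohort ---------------------------------------------------
    t_start = time.perf_counter()
    truth = None
    try:
        if config.cohort_csv:
            cohort = read_cohort_csv(config.cohort_csv)
        else:
            spec = CohortSimSpec(**{**config.sim, "seed": seed_sim})
            cohort, truth = simulate_cohort(spec)
    except (ValueError, OSError) as exc:
        raise PipelineError("simulate", str(exc)) from exc
    n_reports = np.array([s.n_reports for s in cohort])
    intervals = np.array([s.mean_interval_days for s in cohort])
    cohort_stats = {
        "n_patients": len(cohort),
        "n_reports_total": int(n_reports.sum()),
        "reports_mean": float(n_reports.mean()),
        "reports_sd": float(n_reports.std(ddof=1)) if len(cohort) > 1 else 0.0,
        "interval_mean_days": float(np.nanmean(intervals)),
        "interval_sd_days": float(np.nanstd(intervals, ddof=1)) if len(cohort) > 1 else 0.0,
    }
    logger.info(
        "simulate: %d patients, %d reports (%.2fs)",
        len(cohort), int(n_reports.sum()), time.perf_counter() - t_start,
    )
    if out is not None:
        write_cohort_csv(cohort, out / "cohort.csv")
        if truth is not None:
            write_ground_truth_json(truth, out / "ground_truth.json")

    # -- stage: filter ---------------------------------------------------
    t_stage = time.perf_counter()
    freport = apply_inclusion_filter(
        cohort, config.min_reports, config.max_mean_interval_days
    )
    included = [s for s in cohort if s.patient_id in set(freport.included)]
    if not included:
        raise PipelineError("filter", "no patients pass the inclusion filter")
    logger.info(
        "filter: %d included / %d excluded (%.2fs)",
        len(freport.included), len(freport.excluded), time.perf_counter() - t_stage,
    )
    if out is not None:
        (out / "filter.json").write_text(json.dumps(freport.to_dict(), indent=1))

    # -- stage: validate -------------------------------------------------
    # distributional check of the cohort's scores against a clinical-style
    # cross-sectional reference sample, per treatment state
    t_stage = time.perf_counter()
    try:
        xs_spec = CrossSectionSpec(**{**config.cross_section, "seed": seed_xs})
        xs = simulate_cross_section(xs_spec)
        validation = {}
        for state in ("on", "off"):
            cohort_scores = np.concatenate(
                [s.scores[s.labels == state] for s in included]
            )
            ref_scores = xs.loc[xs["state"] == state, "updrs_1_2"].to_numpy()
            if len(cohort_scores) >= 2 and len(ref_scores) >= 2:
                validation[state] = ks_two_sample(
                    cohort_scores, ref_scores, zscore_first=True
                ).to_dict()
            else:  # pragma: no cover
                validation[state] = None
        ages_cohort = np.array(
            [s.age_at_diagnosis for s in included if s.age_at_diagnosis is not None]
        )
        if len(ages_cohort) >= 2:
            validation["age_at_diagnosis"] = ks_two_sample(
                ages_cohort, xs["age_at_diagnosis"].to_numpy(), zscore_first=True
            ).to_dict()
    except ValueError as exc:
        raise PipelineError("validate", str(exc)) from exc
    logger.info("validate: done (%.2fs)", time.perf_counter() - t_stage)
    if out is not None:
        write_cross_section_csv(xs, out / "cross_section.csv")
        (out / "validation.json").write_text(json.dumps(validation, indent=1))

    # -- stage: trend ----------------------------------------------------
    t_stage = time.perf_counter()
    cv_seeds = _derive_seeds(seed_cv, len(included))
    per_patient = {}
    residual_frames = []
    trend_rows = []
    for series, s_cv in zip(included, cv_seeds):
        try:
            model = TrendFilter.from_series(series)
            fit = model.fit_cv(
                n_lambdas=config.n_lambdas, n_folds=config.n_folds, seed=s_cv
            )
        except (ValueError, np.linalg.LinAlgError) as exc:
            raise PipelineError("trend", f"patient {series.patient_id}: {exc}") from exc
        changes = fit.abrupt_changes(config.slope_jump_threshold)
        outliers = fit.outlier_reports(config.outlier_k)
        per_patient[series.patient_id] = {
            "lam_star": fit.lam,
            "objective": fit.objective,
            "duality_gap": fit.duality_gap,
            "knots": fit.knots.tolist(),
            "abrupt_changes": changes,
            "outlier_reports": outliers.tolist(),
            "cv": fit.cv.to_dict() if fit.cv is not None else None,
        }
        frame = compute_residuals(series, fit)
        if config.df_correction:
            n = len(series)
            df_fit = min(len(fit.knots) + 2, n - 3)
            infl = float(np.sqrt(n / (n - df_fit)))
            frame = frame.assign(r=frame["r"] * infl, abs_r=frame["abs_r"] * infl)
        residual_frames.append(frame)
        trend_rows.append(
            pd.DataFrame(
                {
                    "patient_id": series.patient_id,
                    "t_years": series.times,
                    "updrs_1_2": series.scores,
                    "trend": fit.trend,
                    "residual": series.scores - fit.trend,
                }
            )
        )
    trends_df = pd.concat(trend_rows, ignore_index=True)
    trends_summary = {
        "n_patients_fit": len(per_patient),
        "n_with_abrupt_changes": sum(
            1 for d in per_patient.values() if d["abrupt_changes"]
        ),
        "n_with_outliers": sum(
            1 for d in per_patient.values() if d["outlier_reports"]
        ),
        "per_patient": per_patient,
    }
    logger.info(
        "trend: fit %d patients (%.2fs)",
        len(per_patient), time.perf_counter() - t_stage,
    )
    if out is not None:
        trends_df.to_csv(out / "trends.csv", index=False)

    # -- stage: fluctuation ----------------------------------------------
    t_stage = time.perf_counter()
    records = pool_residuals(residual_frames)
    try:
        flu = FluctuationModel(records).fit()
    except ValueError as exc:
        raise PipelineError(
            "fluctuation",
            f"{exc} (n_records={len(records)}, "
            f"n_zero={int((records['abs_r'] <= 1e-8).sum())})",
        ) from exc
    skew = bootstrap_skewness_test(
        records["r"].to_numpy(), B=config.bootstrap_B, seed=seed_boot
    )
    m0, _, _ = flu.predict(0.0)
    m16, _, _ = flu.predict(16.0)
    minimal_cid = scale_cid(MINIMAL_TOTAL_CID)
    moderate_cid = scale_cid(MODERATE_TOTAL_CID)
    cid = {
        "minimal_cid_parts_1_2": minimal_cid,
        "moderate_cid_parts_1_2": moderate_cid,
        "fluctuation_t0_exceeds_minimal_cid": bool(m0 > minimal_cid),
        "fluctuation_t16_exceeds_moderate_cid": bool(m16 > moderate_cid),
    }
    logger.info(
        "fluctuation: beta0=%.4f beta1=%.4f, |r|(0)=%.2f |r|(16)=%.2f (%.2fs)",
        flu.beta0, flu.beta1, m0, m16, time.perf_counter() - t_stage,
    )
    if out is not None:
        (out / "fluctuation.json").write_text(
            json.dumps({**flu.to_dict(), "skewness": skew.to_dict()}, indent=1)
        )

    report = RunReport(
        config={
            f: getattr(config, f)
            for f in RunConfig.__dataclass_fields__
            if f != "out_dir"
        },
        version=__version__,
        cohort=cohort_stats,
        filter=freport.to_dict(),
        validation=validation,
        trends=trends_summary,
        fluctuation=flu.to_dict(),
        skewness=skew.to_dict(),
        cid=cid,
    )
    if out is not None:
        (out / "report.json").write_text(report.to_json())
    return report
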