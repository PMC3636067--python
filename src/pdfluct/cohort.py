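"""Cohort data model for longitudinal UPDRS self-report series.

A cohort is a list of :class:`SymptomSeries`, one per patient, each an
irregularly sampled time series of UPDRS Parts I+II totals (0-68) indexed
by time since diagnosis in decimal years.  Treatment labels (``on``,
``off``, ``unknown``) are carried as per-report metadata; they do not
enter the trend or fluctuation analyses.

The long-format CSV dialect is::

    patient_id,t_years,updrs_1_2,label

with one row per report, rows grouped by patient and sorted by time.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SymptomSeries",
    "FilterReport",
    "VALID_LABELS",
    "DAYS_PER_YEAR",
    "score_parts_1_2",
    "apply_inclusion_filter",
    "read_cohort_csv",
    "write_cohort_csv",
    "read_cross_section_csv",
    "write_cross_section_csv",
]

VALID_LABELS = ("on", "off", "unknown")

#: Fixed calendar conversion used throughout (mean Julian year).
DAYS_PER_YEAR = 365.25

SCORE_MIN = 0
SCORE_MAX = 68  # UPDRS Parts I+II: (4 + 13) items x 4 points


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass
class SymptomSeries:
    """One patient's self-reported UPDRS Parts I+II series.

    Times are years since diagnosis and must be strictly increasing;
    duplicate timestamps (two reports on the same day) are collapsed to a
    single report carrying the mean score, rounded half-up, since the
    trend smoother requires distinct times.
    """

    patient_id: str
    times: np.ndarray
    scores: np.ndarray
    labels: np.ndarray = None
    age_at_diagnosis: float | None = None
    sex: str | None = None

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.scores)
        if self.labels is None:
            labels = np.full(len(t), "unknown", dtype=object)
        else:
            labels = np.asarray(self.labels, dtype=object)
        if len(t) == 0:
            raise ValueError(f"patient {self.patient_id!r}: empty series")
        if not (len(t) == len(y) == len(labels)):
            raise ValueError(
                f"patient {self.patient_id!r}: times/scores/labels lengths differ"
            )
        if not np.all(np.isfinite(t)):
            raise ValueError(f"patient {self.patient_id!r}: non-finite times")
        if np.any(t < 0):
            raise ValueError(f"patient {self.patient_id!r}: negative times")
        bad = set(labels) - set(VALID_LABELS)
        if bad:
            raise ValueError(f"patient {self.patient_id!r}: invalid labels {sorted(bad)}")
        yf = np.asarray(y, dtype=float)
        if np.any(~np.isfinite(yf)) or np.any(yf != np.round(yf)):
            raise ValueError(f"patient {self.patient_id!r}: scores must be integers")
        yi = yf.astype(int)
        if np.any((yi < SCORE_MIN) | (yi > SCORE_MAX)):
            raise ValueError(
                f"patient {self.patient_id!r}: scores outside [{SCORE_MIN}, {SCORE_MAX}]"
            )
        order = np.argsort(t, kind="stable")
        t, yi, labels = t[order], yi[order], labels[order]
        # collapse duplicate timestamps to one report (mean score, half-up)
        if len(t) > 1 and np.any(np.diff(t) == 0):
            uniq, inv = np.unique(t, return_inverse=True)
            merged = np.array(
                [_round_half_up(float(np.mean(yi[inv == k]))) for k in range(len(uniq))]
            )
            first_idx = np.array([np.nonzero(inv == k)[0][0] for k in range(len(uniq))])
            t, yi, labels = uniq, merged, labels[first_idx]
        self.times = t
        self.scores = yi
        self.labels = labels

    def __len__(self) -> int:
        return len(self.times)

    @property
    def n_reports(self) -> int:
        return len(self.times)

    @property
    def mean_interval_days(self) -> float:
        """Average reporting interval in days: span over n-1 gaps.

        Undefined (NaN) for single-report series.
        """
        n = len(self.times)
        if n < 2:
            return float("nan")
        return (self.times[-1] - self.times[0]) * DAYS_PER_YEAR / (n - 1)

    @property
    def span_years(self) -> float:
        return float(self.times[-1] - self.times[0])


def score_parts_1_2(part1_items, part2_items) -> int:
    """Total UPDRS Parts I+II score from item responses.

    Part I (mentation, behavior, mood) has 4 items, Part II (activities of
    daily living) has 13; every item is scored 0 (no symptoms) to 4
    (severe).  The total therefore lies in [0, 68].
    """
    p1 = list(part1_items)
    p2 = list(part2_items)
    if len(p1) != 4:
        raise ValueError(f"Part I requires exactly 4 items, got {len(p1)}")
    if len(p2) != 13:
        raise ValueError(f"Part II requires exactly 13 items, got {len(p2)}")
    for name, items in (("Part I", p1), ("Part II", p2)):
        for v in items:
            if not (isinstance(v, (int, np.integer)) and 0 <= v <= 4):
                raise ValueError(f"{name} item {v!r} not an integer in [0, 4]")
    return int(sum(p1) + sum(p2))


@dataclass
class FilterReport:
    """Outcome of the cohort inclusion filter.

    ``included`` and ``excluded`` partition the input patient ids;
    ``stats`` maps every id to (n_reports, mean_interval_days).
    """

    included: list = field(default_factory=list)
    excluded: dict = field(default_factory=dict)  # id -> reason
    stats: dict = field(default_factory=dict)  # id -> (n, mean_interval_days)

    min_reports: int = 15
    max_mean_interval_days: float = 65.0

    def to_dict(self) -> dict:
        return {
            "min_reports": self.min_reports,
            "max_mean_interval_days": self.max_mean_interval_days,
            "n_included": len(self.included),
            "n_excluded": len(self.excluded),
            "included": list(self.included),
            "excluded": dict(self.excluded),
            "stats": {
                k: {"n_reports": int(n), "mean_interval_days": None if math.isnan(d) else d}
                for k, (n, d) in self.stats.items()
            },
        }


def apply_inclusion_filter(
    cohort, min_reports: int = 15, max_mean_interval_days: float = 65.0
) -> FilterReport:
    """Apply the study inclusion criteria to a cohort.

    A patient is included iff they have at least ``min_reports`` reports
    AND their average reporting interval (first-to-last span over n-1
    gaps) is at most ``max_mean_interval_days``.  Both boundaries are
    inclusive.  Too-few-reports takes precedence as the exclusion reason;
    a single-report series has an undefined interval and is excluded as
    ``interval_too_long`` only when ``min_reports`` <= 1.
    """
    report = FilterReport(
        min_reports=min_reports, max_mean_interval_days=max_mean_interval_days
    )
    for series in cohort:
        n = series.n_reports
        gap = series.mean_interval_days
        report.stats[series.patient_id] = (n, gap)
        if n < min_reports:
            report.excluded[series.patient_id] = "too_few_reports"
        # boundary inclusive, with a relative tolerance so a gap computed as
        # exactly the threshold is not excluded by rounding in the t<->days
        # conversion
        elif math.isnan(gap) or gap > max_mean_interval_days * (1 + 1e-12):
            report.excluded[series.patient_id] = "interval_too_long"
        else:
            report.included.append(series.patient_id)
    return report


_COHORT_COLUMNS = ["patient_id", "t_years", "updrs_1_2", "label"]


def write_cohort_csv(cohort, path) -> None:
    """Write a cohort in the long-format CSV dialect (lossless)."""
    frames = []
    for s in cohort:
        frames.append(
            pd.DataFrame(
                {
                    "patient_id": s.patient_id,
                    "t_years": s.times,
                    "updrs_1_2": s.scores,
                    "label": s.labels,
                }
            )
        )
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=_COHORT_COLUMNS
    )
    df.to_csv(path, index=False)


def read_cohort_csv(path) -> list:
    """Read a long-format cohort CSV into a list of :class:`SymptomSeries`.

    Malformed rows (missing columns, non-numeric fields, scores outside
    [0, 68], unknown labels) raise a :class:`ValueError` citing the
    offending line number (1-based, counting the header as line 1).
    Rows out of time order within a patient are sorted with a warning.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")

    lines = df.index.to_numpy() + 2  # header is line 1

    def parse(col):
        # plain float() is used (not pandas' fast parser) so values written
        # at full precision round-trip exactly
        out = np.empty(len(df))
        for i, v in enumerate(df[col].to_numpy()):
            try:
                out[i] = float(v)
            except ValueError:
                out[i] = np.nan
            if not np.isfinite(out[i]):
                raise ValueError(
                    f"{path}: non-numeric {col} value {v!r} on line {lines[i]}"
                )
        return out

    t = parse("t_years")
    y = parse("updrs_1_2")
    bad = np.flatnonzero((y < SCORE_MIN) | (y > SCORE_MAX))
    if bad.size:
        raise ValueError(
            f"{path}: score {df['updrs_1_2'].iloc[bad[0]]} outside "
            f"[{SCORE_MIN}, {SCORE_MAX}] on line {lines[bad[0]]}"
        )
    bad = np.flatnonzero(~df["label"].isin(VALID_LABELS).to_numpy())
    if bad.size:
        raise ValueError(
            f"{path}: invalid label {df['label'].iloc[bad[0]]!r} on line {lines[bad[0]]}"
        )

    df = df.assign(t_years=t, updrs_1_2=y)
    cohort = []
    for pid, grp in df.groupby("patient_id", sort=False):
        tv = grp["t_years"].to_numpy()
        if np.any(np.diff(tv) < 0):
            warnings.warn(
                f"{path}: rows for patient {pid!r} out of time order; sorting",
                stacklevel=2,
            )
        cohort.append(
            SymptomSeries(
                patient_id=str(pid),
                times=tv,
                scores=grp["updrs_1_2"].to_numpy(),
                labels=grp["label"].to_numpy(),
            )
        )
    return cohort


_XS_COLUMNS = ["subject_id", "age_at_diagnosis", "updrs_1_2", "state"]


def write_cross_section_csv(sample: pd.DataFrame, path) -> None:
    """Write a cross-sectional reference sample (one row per subject)."""
    missing = [c for c in _XS_COLUMNS if c not in sample.columns]
    if missing:
        raise ValueError(f"cross-section frame missing columns {missing}")
    sample[_XS_COLUMNS].to_csv(path, index=False)


def read_cross_section_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in _XS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if not df["state"].isin(["on", "off"]).all():
        bad = df.loc[~df["state"].isin(["on", "off"]), "state"].iloc[0]
        raise ValueError(f"{path}: invalid state {bad!r}")
    return df
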