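"""Distributional validation: z-scoring, q-q pairing, two-sample K-S test.

Used to check that two samples (e.g. a self-reported cohort versus a
clinically scored reference sample) share a distributional form.
Z-scoring first removes location and scale, so the K-S test then probes
shape only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.stats

__all__ = ["KSComparison", "QQPairs", "zscore", "ks_two_sample", "qq_pairs"]


@dataclass
class KSComparison:
    """Two-sample Kolmogorov-Smirnov comparison.

    ``D`` is the supremum ECDF difference; ``p_value`` comes from the
    asymptotic Kolmogorov distribution with effective sample size
    n1*n2/(n1+n2).
    """

    D: float
    p_value: float
    n1: int
    n2: int
    zscored: bool

    def to_dict(self) -> dict:
        return {
            "D": self.D,
            "p_value": self.p_value,
            "n1": self.n1,
            "n2": self.n2,
            "zscored": self.zscored,
        }


@dataclass
class QQPairs:
    """Paired empirical quantiles of two samples at common probabilities."""

    probs: np.ndarray
    q_a: np.ndarray
    q_b: np.ndarray


def zscore(sample) -> np.ndarray:
    """Standardize a sample to mean 0 and (n-1)-denominator SD 1."""
    x = np.asarray(sample, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("z-scoring requires a 1-d sample with n >= 2")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("constant sample has zero standard deviation")
    return (x - x.mean()) / sd


def ks_two_sample(a, b, zscore_first: bool = False) -> KSComparison:
    """Two-sample K-S test with optional per-sample z-scoring first."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both samples need n >= 2")
    if zscore_first:
        a, b = zscore(a), zscore(b)
    res = scipy.stats.ks_2samp(a, b, method="asymp")
    return KSComparison(
        D=float(res.statistic),
        p_value=float(res.pvalue),
        n1=len(a),
        n2=len(b),
        zscored=zscore_first,
    )


def qq_pairs(a, b, n_points: int = 100) -> QQPairs:
    """Empirical quantile pairs at probabilities (i - 0.5) / n_points.

    Quantiles use linear interpolation between order statistics with
    Hazen plotting positions, matching the probability grid.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    if len(a) == 0 or len(b) == 0:
        raise ValueError("samples must be nonempty")
    probs = (np.arange(1, n_points + 1) - 0.5) / n_points
    q_a = np.quantile(a, probs, method="hazen")
    q_b = np.quantile(b, probs, method="hazen")
    return QQPairs(probs=probs, q_a=q_a, q_b=q_b)
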