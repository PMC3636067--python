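"""Independent reference implementations used only to check the package.

These deliberately use different algorithms from the implementation:
the trend problem is solved as an epigraph-form QP by scipy
``trust-constr``, the ECDF supremum by an explicit scan over pooled
points, and quantile pairing by direct order-statistic interpolation.
"""

import numpy as np
import scipy.optimize


def solve_trend_epigraph(times, values, lam, tol=1e-12):
    """Trend filtering as a smooth QP with slack variables.

    minimize 0.5*||y - x||^2 + lam * sum(s)
    subject to -s <= D x <= s, s >= 0,

    solved with scipy's trust-constr; returns (x, objective).
    """
    t = np.asarray(times, float)
    y = np.asarray(values, float)
    n = len(t)
    dt = np.diff(t)
    D = np.zeros((n - 2, n))
    idx = np.arange(n - 2)
    D[idx, idx] = 1.0 / dt[:-1]
    D[idx, idx + 1] = -(1.0 / dt[:-1] + 1.0 / dt[1:])
    D[idx, idx + 2] = 1.0 / dt[1:]
    m = n - 2

    # row-normalize D for conditioning; fold the scale into the penalty
    row_scale = np.abs(D).max(axis=1)
    Dn = D / row_scale[:, None]
    w = lam * row_scale

    def fun(z):
        x, s = z[:n], z[n:]
        return 0.5 * np.sum((y - x) ** 2) + w @ s

    def grad(z):
        x = z[:n]
        return np.concatenate([x - y, w])

    H = np.zeros((n + m, n + m))
    H[:n, :n] = np.eye(n)

    # A z >= 0 rows: s - Dn x >= 0 and s + Dn x >= 0
    A = np.block([[-Dn, np.eye(m)], [Dn, np.eye(m)]])
    con = scipy.optimize.LinearConstraint(A, 0.0, np.inf)
    z0 = np.concatenate([y, np.abs(Dn @ y) + 1.0])
    bounds = [(None, None)] * n + [(0.0, None)] * m
    res = scipy.optimize.minimize(
        fun, z0, jac=grad, hess=lambda z: H, method="trust-constr", constraints=[con],
        bounds=bounds, options={"gtol": tol, "xtol": tol, "maxiter": 5000},
    )
    x = res.x[:n]
    obj = 0.5 * np.sum((y - x) ** 2) + lam * np.sum(np.abs(D @ x))
    return x, float(obj)


def ks_statistic_scan(a, b):
    """Brute-force sup |ECDF_a - ECDF_b| over all pooled sample points."""
    a = np.sort(np.asarray(a, float))
    b = np.sort(np.asarray(b, float))
    points = np.concatenate([a, b])
    d = 0.0
    for x in points:
        fa = np.mean(a <= x)
        fb = np.mean(b <= x)
        d = max(d, abs(fa - fb))
    return d


def quantiles_by_hand(sample, probs):
    """Hazen linear interpolation between order statistics.

    Order statistic k (1-based) sits at probability (k - 0.5) / n;
    queries outside that range clamp to the extremes.
    """
    x = np.sort(np.asarray(sample, float))
    n = len(x)
    out = np.empty(len(probs))
    for i, p in enumerate(probs):
        h = p * n + 0.5  # 1-based fractional order statistic
        if h <= 1:
            out[i] = x[0]
        elif h >= n:
            out[i] = x[-1]
        else:
            k = int(np.floor(h))
            frac = h - k
            out[i] = x[k - 1] * (1 - frac) + x[k] * frac
    return out


def curvature_by_loop(times, values):
    """Direct loop over interior points of the slope-change magnitudes."""
    t = list(times)
    x = list(values)
    total = 0.0
    for i in range(1, len(t) - 1):
        left = (x[i] - x[i - 1]) / (t[i] - t[i - 1])
        right = (x[i + 1] - x[i]) / (t[i + 1] - t[i])
        total += abs(right - left)
    return total
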