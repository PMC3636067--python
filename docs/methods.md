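# Methods

`pdfluct` analyses short-term (days-to-weeks) dynamics of Parkinson's
disease symptom severity in longitudinal self-reported UPDRS Parts I+II
series (integer totals on 0–68, irregularly sampled in time since
diagnosis). The pipeline separates each patient's series into a slowly
varying trend and residual fluctuations, then models how the magnitude
of those fluctuations grows with disease duration.

## Trend model

For one patient with scores `y_i` at strictly increasing times `t_i`
(years since diagnosis), the trend `x` solves

    minimize_x  1/2 Σ_i (y_i − x_i)²  +  λ · Σ_{i=2}^{n−1} |s_i − s_{i−1}|,

where `s_i = (x_{i+1} − x_i)/(t_{i+1} − t_i)` are the divided-difference
slopes. The penalty is the total variation of the slope sequence — a
discrete total absolute curvature — so solutions are exactly piecewise
linear with knots at data points. This is ℓ1 trend filtering
generalised to irregular grids; the unweighted slope-change TV (rather
than interval-length weightings) is what preserves the exact
piecewise-linear structure. The problem is strictly convex, so the
optimum is unique and verifiable.

Assumptions: reports are conditionally independent given the trend;
the trend varies on a timescale of months to years while residuals are
report-to-report; treatment labels do not enter the fit (all reports
are smoothed together).

### Solver

The dual is a box-constrained QP in the `n−2` curvature multipliers
`u` (`|u_j| ≤ λ`): maximise `uᵀDy − ½‖Dᵀu‖²`, with `x = y − Dᵀu`. It is
solved by L-BFGS-B followed by an active-set polish that pins
multipliers at the box edge and solves the free block's KKT system
exactly, iterating pin/release until the sign conditions hold. The
reported duality gap certifies optimality per fit; on random instances
it is ~1e-10 and the objective agrees with an independent epigraph-QP
solve (scipy `trust-constr`) to better than 1e-6 relative.

Limits of the path: `λ = 0` interpolates the data; for
`λ ≥ λ_max` the fit is the OLS straight line. `λ_max` has a closed
form: the OLS residual `r` is orthogonal to `span{1, t} = null(D)`, so
`Dᵀu = r` has a unique solution and `λ_max = ‖u‖_∞`.

### Choosing λ

λ is selected per patient (each individual has enough reports that no
pooling across patients is needed) by K-fold cross-validation:

- grid: 30 log-spaced values on `[1e-4·λ_max, λ_max]`;
- folds: interior reports randomly partitioned into 5 folds; the first
  and last report are never held out, so held-out times are always
  bracketed by retained ones;
- scoring: each held-out report is predicted by linear interpolation of
  the trend fitted to the retained reports at its time; `λ*` minimises
  the mean held-out squared error.

Fold assignment is seeded; the whole fit is reproducible.

Knots are interior points where the fitted slope changes by more than
1e-6 points/year. Abrupt progression changes are knots whose slope
change exceeds a configurable threshold (default 4 points/year);
isolated outlier reports are those with `|residual| > k ×` median
absolute residual of the series (default `k = 3`).

## Fluctuation model

Residuals `r_i = y_i − x̂_i` are pooled across patients with their
report times. Mean absolute fluctuation is modelled with a gamma GLM
(log link, IRLS via statsmodels, Pearson dispersion):

    E[ |r| | t ] = exp(β0 + β1·t).

The log link reflects the empirically straight-line relation between
log mean absolute residual and disease duration; `β1 > 0` is the
heteroscedasticity finding (fluctuations grow with time since
diagnosis). Wald intervals on the linear predictor, exponentiated, give
the CI for the mean at any `t`. Records with `|r| ≤ 1e-8` are dropped
(gamma support is positive) and counted; data lying exactly on an
exponential are handled by a closed-form log-linear shortcut, since
IRLS cannot iterate at zero dispersion.

**Residual degrees-of-freedom correction (pipeline default).** Trend
residuals understate the noise: the fitted trend absorbs part of it,
exactly as an OLS RSS understates σ² without the `n − p` denominator.
For ℓ1 trend filtering the standard unbiased model-complexity estimate
is (number of knots + 2). The pipeline therefore inflates each
patient's residuals by `sqrt(n / (n − df))`, `df = knots + 2` (capped
at `n − 3`), before pooling for the GLM. On ground-truth cohorts this
moves the estimated fluctuation at diagnosis from ≈ 0.85× truth to
≈ 0.95–1.0× truth. It can be disabled (`df_correction=False`);
`compute_residuals` itself always returns plain `y − x̂`.

**Skewness bootstrap.** Signed residuals are tested for asymmetry: B
(default 1000) bootstrap resamples, adjusted Fisher–Pearson skewness of
each, then a t statistic `mean(replicates) / sd(replicates)` with
`B − 1` degrees of freedom, two-sided. The replicate SD is the
bootstrap estimate of the sampling SE of the skewness; dividing it by
√B instead would test the Monte-Carlo error of the bootstrap itself and
reject for any sample whose skewness is not exactly zero.

**CID scaling.** Published clinically-important-difference thresholds
for the total UPDRS (0–176) rescale to the Parts I+II subscale (0–68)
as `68/176 × CID`, rounded half-up to one decimal: minimal 4.3 → 1.7
points, moderate 8.5 → 3.3 points. The pipeline flags whether the
fitted fluctuation at `t = 0` exceeds the minimal CID and at `t = 16`
the moderate CID.

## Distribution validation

Cohort scores (and ages at diagnosis) are compared with a
cross-sectional clinical-style reference sample per treatment state:
both samples are z-scored (n−1 SD), compared on q-q pairs (empirical
quantiles at probabilities `(i−0.5)/n`, linear interpolation between
order statistics — the Hazen convention) and tested with the two-sample
Kolmogorov–Smirnov test using the asymptotic Kolmogorov p-value with
effective size `n1·n2/(n1+n2)`; the sample sizes in scope (hundreds to
thousands) make the asymptotic approximation adequate, and under the
null its nominal-.05 rejection rate measures ~4–5%.

## Synthetic cohort generator

The generator emulates the structure of a high-frequency self-report
cohort and carries full ground truth for recovery testing. Defaults
(one cohort = the study conditions):

| parameter | default | meaning |
|---|---|---|
| `n_patients` | 100 | cohort size |
| `reports_mean / sd / min` | 29 / 14 / 15 | reports per patient (truncated normal) |
| `interval_mean / sd` | 45 / 12 days | gaps between reports (positive truncated normal) |
| `first_report_offset_years` | 1.0 (± 0.3 jitter) | disease duration at first report |
| `age_mean / sd` | 54 / 9 years | age at diagnosis |
| `beta0, beta1` | 0.9555, 0.0512 | residual-magnitude law `E|r| = exp(β0 + β1 t)`, i.e. 2.6 points at `t = 0`, 5.9 at `t = 16` |
| `noise_shape` | 2.0 | gamma shape of the skewed residual law |
| archetype weights | .55/.2/.15/.1 | smooth increase / plateau decrease / abrupt change / outlier spikes |

Truncated normals are *moment-calibrated*: the underlying location is
found by root finding so the delivered (post-truncation) mean equals
the requested one, then sampled by rejection. Naive rejection of
N(29, 14) at ≥ 15 would deliver a mean of ≈ 33, not 29.

Residuals are `r = s(t)·(G − k)` with `G ~ Gamma(k, 1)`: zero mean,
skewness `2/√k > 0`, and `s(t) = exp(β0 + β1 t) / E|G − k|` with the
closed form `E|G − k| = 2 k^k e^{−k}/Γ(k)`, so the mean-absolute law
holds exactly. Observed scores are trend + residual (+ spikes for the
outlier archetype, recorded in the ground truth), clipped to [0, 68]
and rounded to integers. Archetype parameter ranges keep trends within
roughly [5, 55] so clipping is rare.

What the generator does **not** emulate: item-level responses, dropout
and attrition, fluctuation-triggered reporting, within-day on/off
cycling (labels are random metadata), or patients enrolling many years
after diagnosis — disease duration in a generated cohort spans roughly
0.7–8 years, so model predictions at `t = 16` are extrapolations, with
correspondingly wide uncertainty (this is visible in the reported CIs).
Passing recovery tests therefore demonstrate internal consistency of
the pipeline under these idealised conditions, not robustness to the
messiness of real self-report data.

## Numerical choices and degenerate inputs

- Calendar conversion fixed at 365.25 days/year.
- Inclusion filter: mean interval = span/(n−1) in days; both bounds
  (≥ 15 reports, ≤ 65 days) inclusive, with 1e-12 relative tolerance
  at the boundary so day↔year rounding cannot flip a boundary case.
- Duplicate report times collapse to one report with the mean score,
  rounded half-up (the smoother needs distinct times).
- Series with exactly collinear scores have `λ_max = 0`; CV returns
  the interpolating fit directly.
- A cohort whose residuals are all exactly zero (noiseless input) makes
  the gamma GLM stage fail with an informative error — by design, not
  silently.
- Seed fan-out uses `SeedSequence.spawn`, so each stage (simulation,
  cross-section, per-patient CV folds, bootstrap) has an independent
  stream and reports are byte-identical across runs at a fixed seed.
- CSV floats are parsed with exact `float()` so write→read round-trips
  are lossless.

## Problem sizes used in the checks

The calibrated end-to-end recovery uses one 100-patient cohort
(~2 900 reports; about one minute of compute). Solver–oracle
equivalence uses 50 random instances with `n ≤ 20`; K-S null
calibration uses 2 000 replicates of 100-vs-100; skewness power and
GLM power checks use samples of 2 000–2 900 records and 100
replications.
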