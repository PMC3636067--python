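# pdfluct

Short-term dynamics of Parkinson's disease symptoms from longitudinal
self-reported UPDRS data.

Parkinson's disease severity is usually described as changing smoothly
over years. High-frequency self-reports (days to weeks apart) of UPDRS
Parts I+II totals (0–68) make it possible to ask what happens *between*
clinic visits: how large are short-term symptom fluctuations, and do
they grow as the disease progresses? `pdfluct` is a tested pipeline for
that question, aimed at biostatisticians and clinical researchers
working with patient-reported outcome series.

The core pieces:

- **Trend filtering.** Per patient, the trend x̂ minimises
  ½ Σᵢ (yᵢ − xᵢ)² + λ Σᵢ |sᵢ − sᵢ₋₁|, where sᵢ are the
  divided-difference slopes on the irregular time grid — ℓ1 trend
  filtering, giving exactly piecewise-linear fits whose knots mark
  slope changes (including abrupt progression breaks). λ is chosen per
  patient by seeded K-fold cross-validation. The convex solver reports
  a duality gap, so every fit's optimality is verifiable.
- **Fluctuation model.** Pooled detrended residuals r are modelled by a
  gamma GLM with log link, E[|r| | t] = exp(β0 + β1·t), t = years since
  diagnosis; β1 > 0 quantifies growing fluctuation
  (heteroscedasticity). Residual asymmetry is tested with a bootstrap
  skewness t-test; fluctuation magnitudes are compared against
  clinically important differences rescaled from the total UPDRS to the
  Parts I+II subscale (68/176 × CID: minimal 4.3 → 1.7, moderate
  8.5 → 3.3 points).
- **Validation tools.** z-scoring, q-q quantile pairing, and the
  two-sample Kolmogorov–Smirnov test for checking a self-report cohort
  against a clinical reference sample.
- **Synthetic cohort generator.** Because comparable real datasets are
  not public, a calibrated generator produces cohorts with the right
  structure (report counts, intervals, trend archetypes, positively
  skewed residuals whose mean magnitude grows exponentially with
  disease duration) plus full ground truth for recovery testing.

See `docs/methods.md` for the model details and design choices.

## Worked example

Fit one simulated patient and inspect the trend:

```python
from pdfluct import CohortSimSpec, simulate_cohort, TrendFilter

cohort, truth = simulate_cohort(CohortSimSpec(n_patients=3, seed=11))
fit = TrendFilter.from_series(cohort[0]).fit_cv(seed=1)
print(fit.summary())
```

```
Piecewise-linear trend fit
========================================
n reports:        18
lambda:           0.919958
objective:        47.8926
duality gap:      5.4e-13
RSS:              95.7851
curvature:        7.38964e-13
knots:            []
CV lambda* (of 30): 0.919958
```

This patient's cross-validated fit is a straight line (no knots, zero
curvature); the duality gap certifies the solver converged. Residuals
(`fit.residuals`), abrupt-change events (`fit.abrupt_changes(4.0)`) and
outlier reports (`fit.outlier_reports()`) hang off the result.

Run the whole pipeline on the default calibrated 100-patient cohort:

```python
from pdfluct import RunConfig, run_pipeline

report = run_pipeline(RunConfig(seed=0))
print(report.fluctuation["predicted_t0"])
print(report.fluctuation["predicted_t16"])
```

With seed 0 this simulates 100 patients (2 915 reports), filters them
(≥ 15 reports, mean interval ≤ 65 days), fits per-patient trends, and
fits the pooled gamma GLM, giving β̂0 = 0.9338, β̂1 = 0.0558 and

```
{'mean': 2.54, 'ci_low': 2.36, 'ci_high': 2.74}   # |r| at t = 0
{'mean': 6.21, 'ci_low': 4.53, 'ci_high': 8.52}   # |r| at t = 16
```

i.e. an estimated mean absolute fluctuation of ~2.5 UPDRS points at
diagnosis rising to ~6.2 points 16 years later (the generator's truth
is 2.6 and 5.9; t = 16 extrapolates beyond the cohort's observed span,
hence the wide interval). The pooled residuals are positively skewed
(skewness 1.26, bootstrap p ≪ .001), and the fluctuation at diagnosis
already exceeds the scaled minimal clinically important difference of
1.7 points — short-term variability is large enough to matter for
clinical decisions and trial design.

The same stages are available from the shell:

```sh
pdfluct simulate --seed 0 --out run/
pdfluct filter --in run/cohort.csv --report run/filter.json
pdfluct run-all --seed 0 --out run/
```

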