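# coda24 — compositional analysis of 24-hour movement behaviours

`coda24` implements the full computational chain used in paediatric
time-use epidemiology to ask how a child's 24-hour movement-behaviour
*composition* — minutes of sleep, sedentary behaviour (SB), light (LPA) and
moderate-to-vigorous physical activity (MVPA) — differs between groups and
relates to motor competence:

1. **Accelerometry**: raw wrist tri-axial signal (±8 g) → auto-calibration
   against gravity → ENMO (`√(x²+y²+z²) − 1 g`, truncated at 0) averaged
   over 5-s epochs → non-wear detection (per-axis SD < 13 mg or range
   < 50 mg on ≥2 axes, 60-min windows sliding by 15 min) → imputation from
   matching clock times on other days → nightly sleep windows from the
   distribution of change in the z-angle → intensity classification
   (SB ≤ 50 mg < LPA < 200 mg ≤ MVPA) → valid-day filtering (≥16 h wear,
   ≥4 valid days, calibration error ≤ 10 mg) → per-participant mean daily
   compositions for total / weekday / weekend / school (08:45–15:15)
   segments.
2. **Compositional statistics**: a composition carries only relative
   information, so analyses run in isometric log-ratio (ilr) *pivot
   coordinates* built from a sequential binary partition,
   `z_i = √((D−i)/(D−i+1)) · ln(x_(i) / gmean(x_(i+1..D)))`.  The package
   provides closure, multiplicative zero replacement, compositional
   (geometric) means, variation matrices, and the exact inverse transform.
3. **Inference** (statsmodels-style models with `fit()` → results):
   * `CompositionalMANCOVA` — multivariate linear model of the ilr
     coordinates on group + covariates (age, sex, deprivation); group
     effect tested with Wilks' Λ and Rao's F approximation.
   * `IlrRegression` — OLS of motor competence on ilr coordinates +
     covariates; the composition block is tested with a Type II Wald χ²
     and drives **isotemporal substitution**: the predicted outcome change
     when t minutes move from one behaviour to another with the remaining
     behaviours held constant, with delta-method (or bootstrap) CIs.
   * Stratified bootstrap percentile CIs for between-group log-ratio
     differences of compositional means, back-transformed to percentages
     via `(exp(d) − 1)·100`.
   * Pearson χ² tests for lifestyle contingency tables.
4. **Synthetic data**: because the motivating cohort study (69 children,
   30 with suspected developmental coordination disorder) deposited no raw
   data, `coda24.simulate` generates cohorts, daily bout schedules and raw
   tri-axial signals with known ground truth that emulate the published
   group summaries, so every stage is testable end to end.

It is aimed at researchers in physical-activity epidemiology and
biostatistics who want a tested, reusable reference implementation of this
pipeline, or a simulation bench for it.

## Worked example

```python
from coda24 import (CohortSpec, DEFAULT_PARTS, generate_cohort,
                    bootstrap_logratio_differences, fit_ilr_regression,
                    mancova_group_test)

truth = generate_cohort(CohortSpec(seed=1))      # 69 children, 30 sDCD
t = truth.table
comp = t[list(DEFAULT_PARTS)].to_numpy()         # minutes/day, rows sum to 1440
covs = t[["age", "sex_male", "deprivation"]]

print(mancova_group_test(comp, t["group"], covs, basis=truth.basis).summary())
print(bootstrap_logratio_differences(truth.minutes("td"),
                                     truth.minutes("sdcd"),
                                     n_boot=2000, seed=1).summary())
fit = fit_ilr_regression(comp, t["sfdc"], covs, basis=truth.basis)
print(fit.summary())
print(fit.isotemporal("lpa", "mvpa", minutes_grid=[-10, -5, 0, 5, 10]))
```

prints

```
Compositional MANCOVA (group effect on ilr coordinates)
  n = 69, coordinates = 3
  Wilks' lambda = 0.7646
  F(3, 62) = 6.364, p = 0.0008
Bootstrap log-ratio differences (sdcd vs td; B = 2000)
  sleep    -2.6%  [ -11.9%,   +7.4%]
  sb       +5.7%  [  -1.5%,  +13.2%]
  lpa      -6.2%  [ -15.9%,   +4.9%]
  mvpa    -19.4%  [ -27.4%,  -10.6%]
OLS of sfdc on ilr coordinates (pivot = sleep)
  n = 69, df_resid = 62, R^2 = 0.224
  composition block: Wald chi2(3) = 11.750, p = 0.0083
  ...
from_part to_part  minutes  delta_outcome  ci_low  ci_high
      lpa    mvpa     -5.0         -0.735  -1.182   -0.288
      lpa    mvpa      0.0          0.000   0.000    0.000
      lpa    mvpa      5.0          0.690   0.272    1.109
```

Reading the output: in this synthetic cohort the sDCD group spends ~19%
less time in MVPA than typically developing peers (bootstrap CI excludes
0); the composition as a whole predicts motor competence (Wald p = 0.008);
and reallocating 5 min/day from LPA to MVPA predicts a +0.69 (95% CI 0.27
to 1.11) point gain on the 0–24 motor-competence scale.

A CLI mirrors the stages:

```sh
coda24 run --config config.json        # simulate -> process -> analyse
coda24 simulate|process|analyse --config config.json [--seed N] [--out dir]
```

The JSON config is validated strictly (unknown keys are rejected); the
output directory receives cohort/compositions/day-summary CSVs, a
`results.json`, a human-readable `report.txt`, optional figures, and a
provenance block (config hash, seed, versions).

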