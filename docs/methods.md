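# Methods

This note records the models, algorithms and design choices behind
`coda24`, and what its synthetic benchmarks do and do not demonstrate.

## 1. Compositional framework

A day is a 4-part composition x = (sleep, SB, LPA, MVPA) closed to
κ = 1440 min (school segment: 3 waking parts closed to 390 min).  All
analysis happens in isometric log-ratio (ilr) coordinates from a
sequential binary partition in *pivot* form: with the pivot part placed
first,

    z_i = sqrt((D−i)/(D−i+1)) · ln( x_(i) / gmean(x_(i+1..D)) ),  i = 1..D−1,

so z_1 carries all information about the pivot relative to the remaining
behaviours.  Natural logarithms are used throughout (the standard CoDA
convention).  The balance matrix is orthonormal, rows sum to zero, and
`ilr_inv(z) = close(exp(Bᵀz), κ)` is the exact inverse.  Part order is
fixed as (sleep, sb, lpa, mvpa), and rotating the pivot yields the four
bases whose first coordinates cover each behaviour.

Zero handling: log-ratios need strict positivity, so parts below
δ = 1 min (one aggregation unit; config-exposed) are raised to δ with the
remaining parts multiplicatively rescaled to preserve κ.

The compositional mean is the closed component-wise geometric mean; it
commutes with ilr (ilr of the mean = mean of the ilr images), which the
tests use as the module's cross-check oracle.  The variation matrix is
var(ln x_j/x_k) over participants, symmetric, zero-diagonal and
closure-invariant.

## 2. Accelerometer processing

* **Auto-calibration.** Stationary 10-s windows (all-axis SD < 13 mg) are
  collected; per-axis gain and offset are estimated by least squares
  driving the stationary vector norms to 1 g (Levenberg–Marquardt on the
  6-parameter residual; equivalent in spirit to the iterative
  closest-point-on-sphere scheme used by GGIR).  The post-calibration
  error is the mean |norm − 1| over stationary windows, in mg.  With fewer
  than 10 stationary windows the problem is ill-posed and an identity
  calibration is returned with a fallback flag.
* **ENMO.** Per sample `max(‖v‖ − 1, 0)` in g, averaged over 5-s epochs,
  reported in mg.  Truncation happens at sample level.
* **Non-wear.** 60-min windows advanced in 15-min steps; a window is
  off-body when ≥2 of 3 axes have SD < 13 mg *or* ≥2 axes have value range
  < 50 mg (strict inequalities, as printed in the rule this mirrors); the
  window's central 15-min block is flagged, mirroring the reference
  implementation's granularity.  Consequently a gap of length L minutes
  can be detected over at most L − 45 min; minute-level sensitivity ≥ 0.9
  therefore needs L ≳ 8 h, which is the regime the benchmark injects
  (overnight-style removals of 600–720 min; devices in the generator come
  off at quarter-hour boundaries, which also matches the detection grid).
* **Imputation.** Non-worn epochs take the mean ENMO of worn epochs at
  the same 5-s clock slot on the other recorded days; a slot worn on no
  day falls back to the participant's overall worn mean with a warning.
  Imputation acts on ENMO *before* classification (so imputed epochs are
  classified by cut-points), one of two defensible readings of
  "imputed at similar time points"; the alternative (imputing labels)
  is not implemented.
* **Sleep.** Heuristic on the z-angle `atan(z/√(x²+y²))` averaged per
  5 s: absolute successive differences, smoothed by a centred 5-min
  rolling median; still blocks where the smoothed change is below
  15 × (10th percentile of the night's values); blocks < 30 min dropped,
  gaps < 60 min merged, longest block wins.  Search windows are
  noon-to-noon (partial first/last spans included).  Two local choices:
  (a) off-body epochs are excluded from still candidacy — a removed
  device is perfectly still and would otherwise masquerade as sleep;
  (b) a still block spanning ≥ 90 % of its search window indicates a
  degenerate window (constant angle, or a sleep-free partial span) and is
  flagged invalid rather than treated as sleep.
* **Classification and summaries.** Sleep label takes precedence inside
  detected windows; otherwise ENMO ≤ 50 mg → SB, 50–200 exclusive → LPA,
  ≥ 200 → MVPA (boundaries as the printed inequalities dictate).  Analysis
  days are midnight-to-midnight; detected sleep minutes accrue to the
  calendar days they fall in; partial first/last days are dropped.
  Weekend = Saturday/Sunday; the school segment (08:45–15:15) is computed
  on weekdays only.  A valid day has ≥ 16 h pre-imputation wear;
  participants need ≥ 4 valid days and calibration error ≤ 10 mg
  (strictly greater excludes).  Segment compositions are arithmetic means
  of daily minutes over qualifying valid days.

## 3. Inference

* **Group comparison.** The (D−1) ilr coordinates are the multivariate
  response in a linear model on group + age + sex + deprivation
  (deprivation enters as a single ordinal quartile covariate, 1–4).  The
  group effect is tested by Wilks' Λ computed from residual SSCP matrices
  with Rao's F approximation; statsmodels' MANOVA is the independent
  cross-check in the test suite.  The statistic is invariant to the ilr
  basis (basis changes rotate the response space).
* **Which behaviours differ.** d_k = ln m_B,k − ln m_A,k between closed
  group compositional means, back-transformed to percentages
  (exp(d)−1)·100, with percentile CIs from B = 2000 stratified bootstrap
  resamples (within-group, with replacement; single documented seed).
* **Outcome model.** OLS of motor competence on the 3 (school: 2) ilr
  coordinates + covariates (statsmodels OLS).  The composition block is
  tested by a Type II Wald χ² (β'V⁻¹β, df = number of coordinates),
  which is pivot-invariant.
* **Isotemporal substitution.** At a reference composition (default: the
  sample compositional mean of the fitted data; the conventional choice),
  t minutes move from one part to another, the rest fixed; the predicted
  change is (ilr(new) − ilr(ref))·β̂ with a delta-method CI from the
  coefficient covariance on a t reference (df = residual df).  A
  case-resampling bootstrap CI is available behind a flag.  The default
  grid is ±30 min in 5-min steps; offsets driving a part ≤ 0 are
  rejected.  Reallocation effects are *not* antisymmetric (log-ratio
  geometry); they agree in magnitude only to first order.
* **Contingency tables.** Pearson χ² without continuity correction;
  zero-margin rows/columns dropped with a warning; α = 0.05 everywhere,
  no multiplicity adjustment.

## 4. Synthetic-data generator

The generator emulates the motivating cohort of 69 children (39 typically
developing, 30 with suspected DCD, screened by age-banded DCDQ cut-offs:
score < 47 below age 8, < 56 from 8 up; the older band is also applied to
the few children past age 10, for whom no cut-off is published).

* **Compositions.** Participant ilr coordinates are Gaussian around the
  group compositional mean's ilr image, independent across coordinates,
  with SD 0.25.  The published tables print no dispersions, so this value
  was derived from the published inferential statistics: together with a
  residual outcome SD of 5.0 score units it reproduces the reported
  regression R² (≈ 0.15) and the reported 5-min LPA→MVPA reallocation
  estimate *and* CI width (0.56, 95 % CI 0.15–0.99) at n = 69.  The
  published MANCOVA F would instead imply dispersion ≈ 0.4, which is
  inconsistent with that regression precision; the regression-based
  calibration was preferred, so simulated group tests are somewhat more
  significant than the published one.
* **Outcome.** Motor competence (0–24 scale) = 18.5 − 1.56 z₁ − 2.21 z₂
  − 6.78 z₃ + 0.5·age + 0.3·male − 0.2·deprivation + N(0, 5²), clipped to
  the scale (<2 % of draws clip).  The ilr slopes point along the
  LPA→MVPA reallocation direction at the cohort reference composition,
  scaled to the 0.56-unit 5-min effect.
* **Covariates.** Age truncated-normal 8.6 ± 1.6 on [6.9, 11.4]; 55 %
  boys; deprivation quartiles with probabilities (14, 35, 11, 8)/68.
  Lifestyle answers are drawn per group from the published contingency
  proportions.
* **Schedules.** Each day starts with one contiguous nocturnal sleep bout
  (whole-minute totals via largest-remainder rounding; 2–4 posture shifts
  of 8–25°), and waking time is tiled with 2–20-min bouts whose totals
  match the participant's true minutes; ENMO targets are drawn inside
  bands that sit safely within the intensity cut-points (sleep 5–20,
  SB 10–45, LPA 60–190, MVPA 210–350 mg).  Bout-length distributions are
  a free design choice (no published bout structure exists) and are
  config-exposed.
* **Signal.** Per epoch the gravity unit vector follows the bout posture
  plus a reflected random walk (0.03°/epoch in sleep, 3–4.5° awake, zero
  off-body — waking arm movement is what the sleep heuristic keys on); the
  dynamic acceleration is a circle of amplitude A = √((1+t)² − 1)
  orthogonal to gravity at 1 Hz, which keeps every sample's norm at
  exactly 1 + t so the epoch-mean ENMO equals the bout target
  deterministically; 3 mg white measurement noise is added (≤ 3 mg
  off-body, satisfying the stillness criteria by construction); samples
  clip at ±8 g.  Waking postures are confined to |z-angle| ≤ 55° because
  the epoch-mean z-angle loses sensitivity to posture change near ±90°
  under large dynamic amplitude.  Default simulation rate is 20 Hz
  (100 Hz optional); all processing thresholds are in physical units so
  the rate is transparent.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: autocorrelated biomechanical movement (gait,
fidgeting), device-specific noise spectra and temperature drift, irregular
sleep (naps, split nights, bedtime variation across days), short casual
non-wear (< 1 h, which the printed rule cannot detect anyway), seasonal and
schoolday structure beyond the fixed 08:45–15:15 window, and measurement
error in the questionnaires.  Recovery results on this bench are best
read as *internal consistency* of the chain, not field validity.

## 5. Numerical choices and degenerate inputs

Strict boundaries as printed: SD "< 13 mg", range "< 50 mg", ENMO 50 mg →
SB, 200 mg → MVPA, calibration exclusion "> 10 mg".  Closure tolerance
1e-9; ilr round-trip tolerance 1e-9 relative.  The sleep threshold falls
back to "≤ 0" when the 10th percentile is exactly zero (constant-angle
input), which routes degenerate nights to the capped/invalid path.  The
ISM prediction at offset 0 is exactly 0 with a zero-width interval.
Singular design matrices are rejected with the collinear columns named.

## 6. Problem sizes used by the test suite and acceptance script

Chosen as the smallest sizes at which the quantities are stable: type-I
error of the group and composition tests from 1000 null replicates at
n = 69; bootstrap coverage from 500 replicates at B = 500 (acceptance band
0.925–0.975, ≈ ±2.6 Monte-Carlo SEs around 0.95); ISM recovery against the
generating model at n = 69 across a ±30-min grid for three behaviour
pairs; signal round-trips on 7-day weeks at 20 Hz (10 clean participants
plus 3 with injected 600/720-min off-body gaps in the acceptance script;
3 + 3 in the test suite); calibration recovery from ~13 h of stationary
multi-orientation recording with injected offsets (±20/−15 mg) and gain
(1.03) distortions.
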