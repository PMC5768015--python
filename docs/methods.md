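# Methods

## The constraint model

The toolkit predicts per-patient organ-at-risk constraints for liver
radiotherapy from one geometric feature, RTL = V_PTV / V_liver. The
modelling assumption is that, across a knowledge cohort of acceptable
historical plans, normal-liver relative volumes (V5–V30), kidney mean doses
and the cord-PRV maximum dose grow approximately linearly with RTL, while
stomach, small-bowel, heart and esophagus doses are dominated by where the
target sits inside the liver and therefore carry no usable RTL trend.

Three rule families implement this:

1. **Quantile-shifted linear rules** (normal liver). An OLS line
   `y = a + b·x` is fitted to the cohort, then the intercept is lowered by
   the k-th smallest residual with `k = ⌈q·n⌉` (default `q = 0.05`). By the
   order-statistic construction, at least `1 − q` of the training points lie
   on or above the shifted line for any finite `n` — the bound is a
   constraint that ~95 % of historical geometries achieved, which the
   optimizer can push toward without being infeasible for typical anatomy.
   The shift is always non-positive for OLS residuals (they sum to zero), so
   the line moves down or stays put. The direction — down, with coverage
   meaning "historical plans sit above the line" — is this package's
   reading of an ambiguous prescription; `q` is exposed for sensitivity
   analysis, and a warning is raised when `n < 1/q` (quantile poorly
   estimated).
2. **Plain OLS rules** (kidneys, cord PRV). No shift by default; whether the
   original method shifted these is unknown, and per-rule shifting can be
   enabled through the fitting spec.
3. **Median rules** (stomach, bowel, heart, esophagus). The population
   median ("medium value" is read as median; a `central="mean"` switch
   exists because the wording also admits the mean).

Protocol materialization evaluates each rule at the patient's RTL and
rounds half-up to the nearest integer in the rule's display unit (% or
cGy) — segment counts and clinical bound displays are integers, and
round-half-up (rather than banker's rounding) reproduces the reference
worked example, e.g. 40 + 50·0.55 = 67.5 → 68 segments. A rule evaluating
to ≤ 0 (degenerate tiny-target geometry) is clipped to 1 unit with a
warning instead of emitting an impossible bound. The three dose rows of the
reference worked example as printed elsewhere differ from the formula
evaluations by 1–3 cGy (consistent with an RTL of ≈ 0.548 rounded to 0.55
in print); this package follows the formulas.

## Dose-volume computation

Point metrics (Vx, Dx%, mean, max, CI, HI) are computed from **raw voxel
doses**, never from binned curves, so they carry no binning error; the
binned cumulative DVH (default bin width 0.05 Gy) exists for plotting,
export and cohort averaging only. Conventions:

- **Dx%** is the minimum dose received by the hottest x % of the structure,
  by linear percentile interpolation over sorted voxel doses (the ICRU-83
  style usage); D100 % is the minimum voxel dose.
- **Vx** counts voxels with dose ≥ x Gy; absolute volumes multiply the
  fraction by the voxel volume. Voxel counting is also the convention for
  reported cc values — treatment planning systems sometimes interpolate,
  which can differ at sharp gradients.
- **CI** = (V_pres∩PTV / V_PTV)·(V_pres∩PTV / V_pres) with the prescription
  isodose evaluated over the whole grid; an optional external/body contour
  restricts it. A plan with no voxel at prescription returns CI = 0 with a
  warning rather than dividing by zero.
- **Empty structures raise errors** rather than yielding silent zeros,
  which would corrupt cohort fitting downstream.
- Margin expansion (PRV generation) marks a voxel inside the expansion iff
  its center lies within the margin of some true voxel center, using a
  spacing-aware Euclidean distance transform. Voxel-center (not surface)
  distance is the simplest convention that can be verified against a
  brute-force all-pairs check.
- The lateral PTV–liver offset is the center-of-mass difference along the
  lateral axis, +axis 0 = patient left by default; the axis is configurable
  because image orientation is a convention, not a fact of the data.

## Statistical comparison

Plan arms are compared per metric with a two-sided paired t-test
(df = n − 1, significance at p < 0.05, uncorrected by default to mirror
common reporting practice; Holm step-down is available). Zero-variance
differences raise an explicit degenerate-test error at the function level;
the table-level `compare_plans` instead flags such rows as degenerate and
non-significant so a whole report survives one constant metric. Vote
tallies from blind physician review are computed in exact rational
arithmetic, so the three percentages always sum to exactly 100. The
monitor-unit increase ratio defaults to the ratio of cohort means,
100·(mean A − mean B)/mean B, with the mean of per-patient ratios as an
alternative convention.

## Synthetic data: what it does and does not emulate

No clinical plan cohort ships with the package; generators supply data with
the statistical structure the method assumes.

- **Knowledge cohort** (default n = 50): RTL uniform on [0.05, 0.9], a
  range that brackets typical liver targets and the worked example (0.55)
  while keeping all constraints positive. Linear metrics are generated on
  the reference coefficient lines plus Gaussian noise; RTL-independent
  metrics scatter around the reference constants. The noise scales
  (5 percentage points for liver V-metrics; 120, 250 and 400 cGy for left
  kidney, right kidney and cord; 8 and 10 points for stomach V20 and bowel
  V15; 250 and 800 cGy for heart and esophagus) are order-of-magnitude
  choices — the true scatter of the original cohort is not published — and
  all metrics are truncated at 0 to stay physical.
- **Phantom**: ellipsoidal liver, spherical GTV/PTV, cord cylinder, two
  kidney ellipsoids on a 64³ grid at 1 mm; dose is the prescription inside
  the PTV with exponential fall-off `D(d) = P·exp(−d/λ)` outside (λ = 12 mm
  default, `None` for a perfectly conformal step). Voxelized volumes agree
  with the analytic ellipsoid/sphere formulas within 2 % at 1 mm spacing.
- **Paired arms**: arm B = arm A + per-metric shift + noise, for verifying
  that the comparison machinery detects built-in effects and stays
  calibrated under the null.

Passing tests on these generators demonstrate that the *machinery* —
fitting, shifting, materialization, metric computation, test calibration —
is correct under the model's own assumptions. They do not demonstrate that
real liver anatomies follow the linear-in-RTL model, that the published
coefficients transfer to another clinic's practice, or that protocols
produced here are deliverable; those require a local knowledge cohort and
plan review.

## Numerical choices and problem sizes

- OLS via `numpy.linalg.lstsq` on the [1, x] design; exact-recovery tests
  tolerate 1e−9 for float round-off.
- Fitting requires ≥ 3 points and a non-constant predictor; both violations
  raise rather than returning NaN coefficients.
- Determinism: every generator is a pure function of (spec, seed); model
  fitting on the same cohort is bit-identical, and model JSON round trips
  byte-for-byte (sorted keys, fixed indent).
- Test problem sizes — 50–200-patient cohorts, 64³–72³ phantoms, 2000
  null replicates for t-test calibration, 100 replicates for the
  unbiasedness check — were chosen as the smallest sizes at which the
  statistical assertions (3 SE recovery, type-I error 0.05 ± 0.02, 95 %
  coverage) are stable across seeds.

## Known limitations

- Single-feature model: no overlap-volume or distance-to-target histogram
  features; organs without an RTL trend get geometry-blind medians.
- No DICOM-RT I/O; dose grids and masks enter as in-memory arrays (or
  phantoms). No optimizer is driven: the output is the constraint protocol,
  not a plan.
- The coverage shift guarantees training-set coverage, not out-of-sample
  coverage; for small cohorts the 5 % quantile is noisy.
- Whether RTL should use whole liver or liver−GTV in the denominator is a
  modelling choice; whole liver is the default with a switch.
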