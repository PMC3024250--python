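# Methods

## The measurement

`epifract` quantifies the morphologic complexity of epithelial architecture
in stained tissue-microarray (TMA) cores as a box-counting (Minkowski–
Bouligand) fractal dimension, and relates the resulting per-patient score to
survival. The per-core measurement is a five-step procedure:

1. **Background correction.** Stained tissue absorbs light, so the specimen
   is darker than a blank field image acquired under identical conditions.
   The corrected image is `clamp(blank − image, 0)`: stain becomes bright on
   a zero background, and any smooth illumination gradient common to the two
   frames cancels. RGB input is collapsed to luminance (Rec. 601 weights)
   before subtraction.
2. **Evaluability (QC).** A core is evaluable when at least half of it is
   stained: the stained fraction is the proportion of corrected pixels above
   a stain threshold (Otsu's threshold by default, configurable). Cores
   below the minimum are reported as `understained`; all-zero cores as
   `blank`. Specimen folding is not detected automatically; folded cores
   must be excluded by hand.
3. **Threshold sweep.** The corrected grayscale image is binarized at a
   series of intensity thresholds (default: 64 evenly spaced values between
   the 1st and 99th percentile of the nonzero corrected intensities). Each
   binary mask is reduced to its morphological outline: mask pixels with at
   least one unset 4-neighbor, border pixels counting out-of-image neighbors
   as unset.
4. **Box counting in a calibrated window.** For each outline, boxes of edge
   `s` on a single axis-aligned grid anchored at the image origin are
   counted if they contain an outline pixel. The dimension is the OLS slope
   of `log N(s)` against `log(1/s)`, restricted to box sizes whose physical
   edge lies in the 10–50 µm scale window. At the default calibration of
   1.06 µm/px this is a geometric ladder (ratio ≈ 1.25) of 8 integer sizes
   from 10 to 47 px. At least 3 usable scales with positive counts are
   required; outlines with fewer than `min_outline_pixels` (default 100)
   pixels yield undefined estimates. The fit's R² is reported so users can
   audit scaling quality; no R² filter is applied.
5. **Global maximum.** The core's fractal dimension is the maximum of the
   dimension-versus-threshold profile; ties go to the smallest threshold.

Because thresholds are percentile-derived from the corrected image, a global
rescaling of illumination or stain intensity reproduces the same binary
masks and hence the same dimension — the measurement is invariant to
microscope illumination setting and stain intensity by construction.
Estimates are clamped to [0, 2] (the admissible range for plane subsets);
an out-of-range slope logs a warning because it indicates a pathological
fit, not a meaningful dimension.

### Numerical behaviour of the estimator

On rendered reference shapes the pipeline recovers analytic dimensions well
inside the documented tolerances: an order-5 Koch snowflake boundary
(analytic log 4/log 3 ≈ 1.2619) comes out at ≈ 1.262 at 2048 px; a 1-px
circle of radius 400 px at ≈ 0.976; a Sierpinski triangle set (log 3/log 2 ≈
1.585) at ≈ 1.54. Two discretization effects bound the accuracy: boxes
partially straddling a smooth curve inflate counts when the box edge is not
small relative to the curvature radius (hence the circle's small downward
bias), and `ceil`-type edge effects bias short curves (a 1-px line needs a
length of ~2000 px for the slope to settle within 0.03 of 1). The fixture
tests therefore use shapes large relative to the 47-px maximum box.

## Pipeline constants

| parameter | default | meaning |
|---|---|---|
| `calibration` | 1.06 µm/px | pixel pitch at 10× objective with 0.63× coupling |
| `scale_window` | (10, 50) µm | physical box-edge range entering the regression |
| `n_thresholds` | 64 | intensity thresholds in the sweep |
| `min_stained_fraction` | 0.5 | QC evaluability minimum |
| `min_outline_pixels` | 100 | smallest outline that yields an estimate |
| `horizon_years` | 10 | survival horizon for KM rates and ROC |
| `cv_split` | 0.5 | training fraction of the split-sample validation |

The scale window is treated as a validated constant of the method and is
configurable but not re-derived here.

## Patient-level analysis

Each patient contributes up to three 0.6-mm cores; the **maximum** core
dimension represents the patient, on the rationale that the most complex
core is the most probable sample of the least differentiated, most
aggressive tumour tissue. Core relatedness is summarized by a one-way
random-effects intraclass correlation on unbalanced groups (Searle's `n0`
correction), implemented directly since installed packages cover only
balanced designs.

Patients are stratified by two **data-oriented cutpoints**: the upper
quartile of the patient-level scores, then the median of the values at or
below it. Quantiles use linear interpolation between order statistics
("type 7"); both boundaries belong to the intermediate stratum, matching
the reporting convention `< c1 / c1–c2 / > c2`. Outcome-oriented
(minimum-p) cutpoint searches are deliberately out of scope.

Associations between category and the six binary clinicopathological
covariates (age ≤/> 55 y, tumour ≤/> 2 cm, grade 1&2 vs 3, nodal status, ER
status, HER-2/neu status) use Pearson chi-square without continuity
correction; small expected cells log a warning rather than switching tests.

## Survival analysis

Kaplan–Meier curves (with the 10-year rate read off the step function),
unweighted k-group logrank tests, and Cox proportional-hazards models with
Efron tie handling are delegated to lifelines; Wald 95% CIs and p-values are
reported and the reference level of every categorical covariate has hazard
ratio 1 by construction. Only Efron tie handling is available — the
partial-likelihood backend does not implement Breslow, and ties are
measure-zero under the simulated continuous follow-up anyway.

**Proportionality check.** The log(−log S(t)) curves per stratum should be
parallel under proportional hazards. Raw crossing counts of Kaplan–Meier
curves are dominated by step noise (early in follow-up the variance of
log(−log S) is enormous), so the implemented rule standardizes the pairwise
curve difference by its Greenwood variance and flags `suspect` only when
some pair separates significantly (|z| > 2) in *both* directions after the
first decile of event times, with the comparison capped at the last time
every stratum retains at least 5 subjects at risk (beyond it the estimate is
a flat extrapolation). Under exact proportional hazards the flag is `ok`
in 10/10 simulation seeds; under crossing Weibull hazards (shapes 0.5 vs 2)
it is `suspect` in 10/10.

**Prognostic accuracy.** The score for ROC analysis is the Cox-predicted
event probability `1 − S(horizon | x)`; the comparative standard is the
observed event indicator, so subjects censored without the event count as
non-events (a deliberate, documented simplification — no time-dependent
ROC). AUC is the Mann–Whitney rank statistic with ties counting ½.

**Missing covariates** are filled by predicted-mean single imputation: a
regression of the target on the fully observed covariates over complete
cases (logistic for binary targets, the predicted probability mapped to the
nearer category). Imputed counts per variable are logged so imputation bias
can be checked by re-running on complete cases.

**Split-sample cross-validation** splits the cohort at random into training
(round(n·fraction)) and validation sets, fits in training, applies the
training coefficients unchanged to the validation covariates, and reports
`shrinkage = AUC_training − AUC_validation` (exact bookkeeping, no
re-estimation). |shrinkage| < 0.10 marks the model generalizable, in which
case a final fit on the combined sample is also returned.

## Synthetic data

No imaging or patient data are distributed; the `synthetic` module generates
every input, as pure functions of spec + seed (bit-reproducible).

**Fixtures** (line, circle, rectangle, Koch snowflake, Sierpinski triangle)
are rendered without anti-aliasing and carry their analytic similarity
dimension. The Koch boundary is the closed triadic curve (all three sides),
1-px stroke; recursion depth is capped so the smallest segment spans ≥ 2 px.

**Pseudo-tissue** stands in for pan-cytokeratin-stained TMA cores: randomly
placed epithelial-like blobs, each a closed contour `r(θ) = r0(1 + Σ a_k
cos(kθ + φ_k))`, are filled until ~60% of the frame is stained. A single
`complexity` dial in [0, 1] controls the number of harmonics (3→20), their
amplitude, and the amplitude/graininess of within-blob stain texture, so
boundary crenellation — and hence pipeline FD — rises monotonically with the
dial (medians ≈ 1.19 / 1.40 / 1.65 at 0 / 0.5 / 1 over 20 seeds at 512 px).
Both frames share a smooth illumination gradient plus mottle; the specimen
is darker than the blank wherever stained. What it does **not** emulate:
nuclei-level texture statistics of real chromatin, stain chemistry,
specimen folding, and out-of-focus blur — so passing tests establish the
pipeline's measurement properties, not clinical performance on real slides.

**Cohorts** draw the patient-level fractal dimension from a Beta(2.4, 1.6)
scaled to [1.08, 1.97], chosen to reproduce the reported score range with
median ≈ 1.62 and quartiles ≈ 1.47/1.77. Per-core scores are the patient
score plus Gaussian deviations re-anchored so the per-patient maximum equals
the drawn score (keeping the patient-level law exact); the deviation
variance is set from the between-patient variance to target an intraclass
correlation of 0.51 (realized ≈ 0.47 after the re-anchoring; the icc dial is
exact at its endpoints). Cores per patient follow the observed evaluability
mix (9.5% / 27.7% / 62.8% for 1/2/3 cores). Survival times are exponential
under a proportional-hazards model with category hazard ratios (1, 2.0,
3.5 by default) and covariate effects echoing the adjusted disease-specific
estimates; an independent competing other-cause death stream separates
disease-specific from overall survival (`dss_event = 1` implies
`os_event = 1`), and exponential censoring is tuned so the expected censored
fraction matches `censoring_rate` for the average subject. Missingness is
injected completely at random at the observed per-variable rates (grade
15/379, node 4/379, ER 15/379, HER-2 12/379).

## Problem sizes used in the test suite

Fixture recovery runs at 2048 px (Koch), 1024 px (circle, Sierpinski);
invariance and monotonicity checks use 512-px pseudo-tissue over 10–20 seeds
per condition; Cox recovery uses 200 replicates of n = 400 with 30%
censoring; logrank calibration 500 replicates of 2×200; ICC calibration 500
patients × 3 cores. These sizes give Monte-Carlo error comfortably inside
the asserted tolerances while keeping the default suite fast.

## Known limitations

- Box counting uses a single origin-anchored grid; offset minimization
  (which reduces the small positive bias on sparse sets) is not enabled by
  default.
- The ROC treatment of censoring is the naive observed-event rule; with
  heavy censoring before the horizon the AUC is attenuated.
- Predicted-mean imputation is single imputation; standard errors downstream
  do not reflect imputation uncertainty.
- The evaluability rule sees only the stained fraction; folded or debris-
  laden cores must be excluded via a manual list.
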