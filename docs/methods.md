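# Methods

This note records the modelling and numerical choices behind the package,
in the order the pipeline applies them.

## Normative reference

The reference is built from the healthy R group only. For each modality
(macular GCC grid, circumpapillary NFL profile) it stores per-location
means and sample (n−1) SDs, and a scalar table of (mean, SD) for every
diagnostic variable the pipeline standardizes: overall/superior/inferior
mean thickness, GLV and FLV per modality, and the disc metrics. A
variable that is numerically constant across reference eyes cannot be
standardized and is dropped from the table with a warning; zero variance
at any *map location* is treated as a degenerate input and is an error.

Significance of loss-direction deviations is one-sided in the thinning
direction (the index targets loss): p > 0.05 normal, 0.01 < p ≤ 0.05
borderline, p ≤ 0.01 outside normal limits, with a p exactly at a cutoff
assigned to the more severe category. The null is Gaussian per location
by default; an empirical-percentile null (smoothed (r+1)/(n+1) rank) is
available for small-n robustness.

## Loss statistics

With FD(loc) = (measured − normative mean)/normative mean:

- **GLV** = 100 · Σ max(−FD, 0) / n_locations — average fractional tissue
  loss, percent of normal. Locations above the mean contribute zero, so
  GLV is monotone under thinning.
- **Pattern deviation** rescales the map by the single factor matching
  its overall mean to the reference overall mean, then recomputes FD.
  Uniform thinning of any magnitude maps to zero by construction; what
  remains is focal (shape) loss.
- **FLV** = 100 · Σ max(−FD, 0) over locations whose pattern deviation is
  significantly low / n_locations. By default the *full* fractional
  deviation is summed at significant locations, so FLV reads as percent
  of normal tissue lost focally; a flag sums the pattern deviation
  instead (scale-invariant variant, for sensitivity analysis).

**Pattern null.** The significance test for FLV cannot use the raw
per-location SD: that SD is dominated by between-eye global-scale
variation, which the rescaling removes, so healthy eyes would almost
never reach significance and FLV would be degenerate in normals. The
reference therefore also stores the per-location mean and SD of the
*rescaled* reference maps, and pattern significance is tested against
that null (falling back to the raw SD where the pattern SD is exactly
zero, e.g. references built from pure scalings of one shape). The FLV
cutoff is p ≤ 0.05, config-exposed.

All statistics weight locations equally and ignore dimensionality, so
the 1-row NFL profile and the 2-D GCC grid are handled by the same code.
No anatomical sampling-density weighting is attempted.

## Two-stage index

Stage 1 fits, per variable group (overall, superior, inferior, GLV, FLV),
a bivariate logistic model on the R-standardized NFL and GCC members;
the weight share of each member is |coefficient| / Σ|coefficients| × 100
and the composite is the correspondingly weighted z-score. Stage 2 is a
maximum-likelihood logistic fit of disease on composite overall thickness
(z-scale), composite FLV (raw % scale, built with the FLV group's
weights) and raw VCDR. These scales mirror the published coefficient
set, whose odds ratios are quoted per 10 μm of thickness, per 1% FLV and
per 0.1 VCDR; display conversions in `odds_ratios()` are exact and
unit-annotated. Standardized weight shares are absolute coefficients
multiplied by the predictor's sample SD, normalized to 100; the
convention reproduces the approximately even three-way split of the
published instance (38/28/34).

Wald standard errors and p-values come from the observed information
(statsmodels `Logit`). On separation or non-convergence the fit falls
back to a weakly L2-penalized logistic regression (C = 10) with a loud
warning; penalized fits report no Wald inference. Fits are invariant to
dataset duplication up to solver tolerance. A warning is raised below
ten events per predictor.

Calibration uses the Hosmer–Lemeshow decile-of-risk test with
χ²(bins − 2); tied deciles are merged with a warning. The bins−2 degrees
of freedom presume estimated probabilities, so calibration checks apply
to fitted scores.

## Evaluation

Higher score = more diseased; an eye is abnormal at or above the
threshold. AUC is the trapezoidal area over all unique thresholds (equal
to the tie-corrected rank statistic). Partial AUC over specificity
90–100% is reported unnormalized (maximum = band width 0.1), with linear
interpolation of sensitivity at the band edges; McClish standardization
is an optional output. `sensitivity_at_specificity` returns the smallest
threshold whose empirical specificity meets the target, falling back to
the most specific operating point when the target is unreachable.

Cross-validation holds out one **subject** at a time (both eyes
together), refitting stage 1 and stage 2 inside every fold; the normative
reference is fixed, mirroring a design with a separate reference subset.
Eye-level folds are available for comparison. Paired AUC comparison uses
a subject-stratified bootstrap (class-stratified resampling of subjects,
two-sided percentile p centred at the null) rather than an eye-level
analytic test, because eyes within subject are correlated; an exact
within-subject permutation test is available and exhaustive up to 14
subjects. `loo_cv_scores` accepts an optional second copy of the feature
table used only when scoring held-out eyes, which supports leakage
audits: corrupting a subject there must change only that subject's
out-of-fold score and must leave its fold model bitwise unchanged.

Severity-stratified reporting computes, per stage bin (<1, 1, 2, 3,
4–5), the AUC of that bin's cases against all controls and the
sensitivities at cutoffs fixed from the full control set.

## Severity staging

Stages are assigned on the (MD, PSD) plane into seven ordered categories
(0, borderline, 1–5). Boundary curves are configuration data; the
shipped default uses L-shaped piecewise boundaries — the assigned stage
is the worse of an MD-threshold stage (cuts −0.5, −1.5, −2.8, −5.0,
−7.8, −12.0 dB) and a PSD-threshold stage (cuts 1.7, 2.4, 3.2, 5.2, 8.0,
11.5 dB) — which makes the classification monotone in each index and
puts boundary points on the more severe side (conservative for
screening). The default cuts were chosen analytically so that the
generator's stage-conditional uniform boxes reproduce a referral-cohort
glaucoma population: with the default stage mix, the implied MD mixture
mean is −5.1 dB and the PSD mixture mean 5.4 dB. Inputs outside the
supported range (MD below −18 dB, PSD above 16 dB) are clamped with a
warning. The defect-type axis (generalized/localized/mixed) is only
classified if curves for it are supplied; stage-only operation is the
default.

## Synthetic cohorts

The generator emulates a 2:1 case-control FD-OCT study: defaults are 105
reference eyes, 118 normal test eyes, 236 perimetric-glaucoma eyes, with
group-specific bilateral-enrolment probabilities (0.72/0.97/0.42) giving
realistic subject counts. Normal (MD, PSD) are Gaussian (−0.1 ± 1.0,
1.4 ± 0.2 dB). Glaucomatous eyes draw a stage from the default mix
(≈0.4%/1.3%/38%/20%/19%/17%/4% over the seven categories), then (MD,
PSD) uniformly inside that stage's boundary box — so classification
round-trips exactly — and then structural loss:

- diffuse thinning of 2% per dB of MD loss (capped at 60%);
- a Poisson number of wedge defects (mean 0.4 × numeric stage), each
  covering 3–12% of the map at 20–70% depth, landing inferior with 2:1
  odds, applied congruently to the GCC wedge and the NFL arc;
- VCDR = N(0.43, 0.10) + 1.2 × total fractional loss, clipped to
  [0.02, 0.98]; horizontal ratio and rim volume are derived with noise.

Healthy maps are a fixed anatomical shape (perifoveal GCC ring; NFL
double hump) times a subject-level scale factor (SD 6%) shared by both
eyes, times an eye-level factor (SD 3%), plus 2 μm additive measurement
noise. The subject factor is what makes subject-level CV meaningfully
different from eye-level CV. Default grids are a 32×32 macular square
with a circular mask split into hemifields, and a 1×128 circumpapillary
profile; all statistics are resolution-independent and the shapes are
config parameters.

The generator does **not** emulate OCT speckle, segmentation failure,
signal-strength artifacts, axial-length or corneal-thickness effects, or
demographic confounding (age/sex/ethnicity are generated but disconnected
from the index, mirroring a frequency-matched design). Passing tests on
this generator therefore demonstrate the statistical machinery — not
device-level accuracy on real scans, where deviations from the assumed
structure-function coupling will lower performance.

## Problem sizes and runtime choices

Unit tests run reduced geometries (8×8 to 16×16 grids, 16–32 sample
profiles) and reduced cohorts; the headline cross-validation checks and
the acceptance script use the full default cohort (459 eyes, 32×32 +
1×128 grids, ~290 subject-level folds). Parameter-recovery checks use
200 replicates of n = 2000 eyes generated from the published
coefficients. Bootstrap AUC comparisons default to 2000 resamples
(500 inside the pipeline report). The full test suite completes in
about a minute; the acceptance script in a few seconds.

## Known limitations

- Stage-1 weights are fit at eye level, ignoring within-subject
  correlation (as is conventional for AUC-oriented analyses); the CV
  design, not the fitter, carries the clustering.
- The default staging boundaries are this package's own calibration, not
  a transcription of any published staging system; supply your own
  curves via `StageBoundaries`/YAML for clinical use.
- FLV/GLV here are defined over equal-area map locations; no claim of
  numeric equality with any device's proprietary normalization is made.
- The bootstrap AUC p-value is percentile-based and can be conservative
  at very small subject counts; use the permutation method there.
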