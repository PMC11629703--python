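# Methods

## Overview

`wmhlnm` implements lesion network mapping (LNM) for white matter
hyperintensity (WMH) masks: per-ROI seed maps are built from normative
connectome data, lesion masks are scored against them, the resulting
feature matrices feed a cross-validated ridge benchmark against volumetric
lesion features, and ROI-level permutation GLMs with spin tests localize
the effects. Because the package must be fully exercisable without patient
or connectome data, a synthetic cohort generator produces a toy brain with
known ground truth; its defaults define the study conditions that the test
suite's calibration and recovery checks are run under.

## Data model and coordinate conventions

All volumes live on one shared grid (`Volume3D`: data + voxel size + world
origin), RAS-like with the left hemisphere at negative x and voxel
`(0,0,0)` centred at the origin. Cross-volume operations require exact grid
equality; there is no implicit resampling, because the intended inputs are
masks already normalized to a single template grid and silent resampling
would hide registration errors. The midline is the x = 0 mm plane; voxel
centres exactly on it belong to neither hemisphere.

`Parcellation` registers cortical, subcortical and tract ROIs. Cortical
and subcortical ROIs share a label volume; tracts overlap one another, so
they are backed by per-tract binary masks. Cortical ROIs carry one of the
seven canonical resting-state networks and a unit-sphere centroid (used by
the spin null).

## LNM scores

Functional seed maps: per reference subject, the mean ROI time series is
Pearson-correlated with every brain voxel's series; r is clipped to
|r| ≤ 1 − 1e−7 (atanh diverges at ±1), Fisher-transformed, and averaged
across subjects. Zero-variance voxel series get z = 0. Scores are computed
on the group-mean z map without back-transforming to r: z is strictly
monotone in r, so which voxels count as "positive" and the ranking used by
the intensity thresholds are identical in either unit; only the numeric
scale differs, and downstream models standardize features anyway.

Scoring rules, in order: collect seed-map values at lesion voxels; if the
threshold fraction f < 1, keep the ⌈f·n⌉ highest-intensity values (lowest
for negative polarity), ties broken by a stable sort on (value, voxel
index) for reproducibility; then functional-positive scores average the
values > 0, functional-negative the values < 0, structural scores average
all selected values. A lesion with no voxel of the requested sign yields an
informative 0 with an `empty_selection` flag (the feature matrix stays
complete); an empty lesion mask yields a missing value with a patient-level
flag — distinct from zero — and such patients are excluded downstream.

The penumbra option dilates the lesion by a Euclidean ball in mm (default
radius 2 voxel widths, anisotropic voxels respected) before scoring,
optionally excluding the original lesion voxels. This is a deliberate,
simple proxy for the normal-appearing white matter adjacent to visible
lesions; no claim is made that it matches any particular published
construction, and both the radius and the exclude-core switch are exposed.

Structural thresholding keeps the highest streamline counts, by symmetry
with the functional rule.

## Synthetic cohort

The generator emulates the *structure* of a memory-clinic LNM study at
desk scale; one master seed fixes brain, connectomes, lesions and
cognition (stage seeds are derived by stable SHA-256 hashing of the stage
name, keeping stages independently reproducible).

* **Toy brain** — 24³ voxels at 1 mm. The cortex is a spherical shell
  (radii ≈ 8–11 mm) partitioned into 40 nearest-direction (spherical
  Voronoi) patches, hence contiguous parcels with unit-norm centroids;
  networks are nearest-direction groups of parcel centroids, hence
  spatially coherent, which the spin null needs to be meaningful. Four
  subcortical blobs sit in the interior; eight tracts are curved tubes
  (quadratic Bézier bent toward the centre) between cortical parcel pairs,
  overlapping each other as real tract atlases do.
* **Functional connectome** — S = 20 reference subjects × T = 100 time
  points (group-averaging behaviour is what matters, not the reference
  sample size). Voxel series are √ρ·(network latent) + √(1−ρ)·noise with
  ρ = 0.6, so same-network voxels correlate at ≈ρ and cross-network at ≈0.
  Interior voxels inherit the network whose mean direction is closest to
  their radial direction, making white matter voxels carry network-specific
  signal — the property that lets lesion position drive network-specific
  fLNM scores.
* **Structural maps** — Poisson counts with intensity density·exp(−d/decay)
  (density 40, decay 1.5 mm) around the tubes of tracts linked to the ROI;
  ROIs with no linked tract have all-zero maps.
* **Lesions** — per-patient voxel counts are log-normal (median 60 voxels,
  σ = 0.7), the right-skewed shape reported for memory-clinic WMH loads,
  emulated at toy scale rather than in absolute ml. Masks are unions of
  blobs with a periventricular spatial prior (70% of blob centres drawn
  near the centre), restricted to white matter so lesions never touch
  cortical parcels — LNM scores therefore reflect remote connectivity, not
  direct cortical damage. The final blob is trimmed from its rim so counts
  follow the clipped log-normal exactly. Empty draws are resampled; every
  patient has a nonzero lesion load, as in a memory-clinic cohort.
* **Demographics and cognition** — age ~ N(71.7, 8.9), sex ~
  Bernoulli(0.5) coded 0/1, education ~ N(12.9, 4.45) clipped at zero.
  Domain scores are b_age·z(age) + b_sex·sex + b_edu·z(education) +
  β·z(network-mean LNM score) + N(0, 1), with defaults β = −0.4 on the
  dorsal-attention network for attention/executive (the recovery-test
  condition), −0.3 for processing speed, −0.4 ventral-attention for verbal
  memory, and no network effect for language. Optional per-domain
  missing-at-random masking is off by default.

What the generator does **not** emulate: MRI physics, partial-volume and
registration error, scanner/site effects, cohort harmonization,
anticorrelated BOLD networks (cross-network correlation is ~0, not
negative), and realistic lesion texture. Passing tests therefore show the
*pipeline* is correct and calibrated under known ground truth, not that
real WMH cohorts behave this way.

## Prediction benchmark

Nested cross-validation: outer 10-fold × 10 repeats (100 scores per
feature set and domain), inner 5-fold for tuning α on
{0.001, 0.01, 0.1, 1, 10, 100, 1000}. The outer fold count matches the
published design; the inner depth is unspecified there, and 5 is the
conventional, cheaper choice. Folds stratify the continuous target via 10
quantile bins. Continuous features (age, education, all imaging features)
are z-scored with training-fold statistics only; binary sex is left
unscaled. Alpha is selected by mean inner-fold Pearson r (consistent with
the outer scoring), ties toward the smaller alpha. Ridge solutions are
exact, via one SVD of the centred training matrix evaluated across the
whole alpha grid — this is what keeps the calibration suites (hundreds of
full nested CVs) tractable. Patient filtering is per-domain complete-case
on the target; features are never imputed. Constant features within a
training fold get unit scale (they contribute nothing); a constant
training target flags the fold and its score is missing.

Model comparison uses the corrected resampled t-test,
t = d̄ / √((1/K + n_test/n_train)·s²_d), df = K−1, where the n_test/n_train
term inflates the variance to account for overlapping training sets. A
difference vector with (numerically) zero variance but nonzero mean is
reported as degenerate with p = 1/K.

Two small-sample behaviours of fold-wise Pearson scoring are worth
knowing. First, with very small stratified test folds (≲ 8 points) each
fold spans the full target range and fold-wise r is *inflated*; learning
curves can then look non-monotone. The learning-curve default (20%–100% in
10% steps; 1% steps by config) should be read with fold sizes in mind.
Second, cross-validated null predictions carry a dataset-conditional bias
in fold-wise r that differs between feature sets and persists across folds
and repeats; no resampled t-test can average it away, so with Pearson
scoring the corrected test remains measurably liberal at desk scale. With
squared-error scores (negative MSE, sum-of-squares R²) — the setting the
corrected test was derived for — it is nominal-to-conservative while the
naive paired t-test is heavily anti-conservative. The calibration check in
the test suite therefore exercises the corrected test on negative-MSE
scores; comparisons of Pearson scores between feature sets should be read
as conservative-by-construction only in their variance term, with this
residual caveat in mind.

## ROI-level inference

Per ROI: y, the ROI score, age and education are z-scored (sex 0/1
unscaled) and an OLS of y on [1, x_roi, age, sex, education] gives the
standardized β and its t. The permutation null is Freedman–Lane — permute
the residuals of the covariates-only model, re-residualize against the
covariates, recompute every ROI's t — the default scheme of the standard
permutation-GLM tooling; the observed t is computed by Frisch–Waugh
residualization, which equals the full-model OLS t exactly and vectorizes
across ROIs × permutations. p-values carry the +1 correction (never zero);
FWE control is single-step max-|t| across the ROIs of one modality ×
domain family (the canonical permutation FWE; where the published family
boundary is ambiguous, one GLM family = one score matrix).

Spin test: each spin applies one uniform random 3-D rotation to the
cortical parcel centroids; each parcel takes the β of its nearest rotated
neighbour (ties to the lower roi_id); network means are recomputed and a
two-sided p compares |null mean| to |observed mean| with the +1
correction. The toy cortex is a single closed shell, so one rotation
serves both hemispheres; for a two-hemisphere parcellation the standard
practice of mirroring the rotation for the left hemisphere would apply —
the centroid-based nearest-neighbour variant was chosen over vertex-level
spinning because the toy parcels are centroid-defined. Subcortical and
tract ROIs are reported without spin p (the networks are cortical).

## Pipeline

`RunConfig` (YAML, unknown keys rejected; threshold fraction restricted to
{1.0, 0.5, 0.25}) drives simulate → lnm → predict → infer; each stage
reads only prior stages' on-disk artifacts (NIfTI volumes, TSV + JSON
schema tables, `.npz` connectome), so runs are byte-reproducible and
resumable. A run directory's report records file manifests, wall times,
package version and a config hash; rerunning with a different config into
the same directory requires `force`.

## Problem sizes used by the test suite

Unit tests run on the default 24³ toy brain (52 ROIs). Calibration checks
use 50-ROI/n = 200 nulls with 1000 permutations × 20 replicates for the
FWE test, and 200 simulated null datasets for the corrected-t-test check.
Recovery checks use 20 replicate cohorts of n = 400 with β = −0.4. These
sizes were chosen so the full statistical behaviour (FWE level, spin
specificity, effect recovery) is measurable on a laptop-class machine.

## Known limitations

* The toy brain has one cortical shell, not two hemispheric sheets;
  hemisphere handling is exercised, but midline anatomy is not realistic.
* Structural "tractography" is a distance-decay Poisson field, so sLNM
  scores have no fibre-orientation structure.
* The corrected resampled t-test is a heuristic; with correlation scoring
  it is only approximately calibrated, and only for adequately sized test
  folds (see above).
* The published analysis' absolute performance values depend on a 3485-
  patient clinical dataset and real connectomes; desk-scale runs reproduce
  the *pattern* (LNM features beat volumetric features when effects are
  connectivity-mediated; localization to the seeded network), not the
  absolute correlations.
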