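# Methods

## Geometry and conventions

All volumes share one reference grid (shape, 4×4 affine); nothing is
resampled, and joint operations require bit-equal shapes and affines
within 1e-6 — mirroring practice where all images are normalized to a
single 2-mm standard space first. Voxel indices are 0-based; world
coordinates are mm. A continuous voxel coordinate belongs to integer
index *i* iff it lies in the half-open cell [i − 0.5, i + 0.5) per
axis, so exact .5 boundaries round up deterministically.

Smoothing is parameterised by FWHM (mm), the neuroimaging convention,
with sigma = FWHM / (2√(2 ln 2)) per axis in voxel units (anisotropic
voxels supported). The kernel is truncated at 4 sigma with zero
padding and no boundary renormalisation, which keeps smoothing exactly
linear and sum-conserving for interior signal. An "8 mm Gaussian
kernel" is read as 8 mm FWHM; if a user means sigma they can pass
`fwhm_mm = sigma * 2.3548`.

## Fiber voxelization

Fibers are rasterised with the classic driving-axis 3D Bresenham line
between consecutive polyline-point voxels (26-connected). Guaranteed
postconditions: endpoint inclusion, per-axis monotonicity, path length
= Chebyshev distance + 1, and every path voxel within max-norm 1 of
the continuous segment. Corner-touching voxels may be skipped; a
supercover variant (`segment_voxels_supercover`) exists for
sensitivity analyses. Per-fiber voxels form a *set*: a fiber looping
through the same lesion voxel twice scores it once.

Two documented non-invariances of the classic algorithm: the path is
not generally symmetric under endpoint reversal (it is for axis-aligned
and main-diagonal segments), and inserting collinear midpoints into a
polyline can shift the rasterised path by one voxel (the voxel sets
stay within max-norm distance 1). Both are properties of Bresenham
rasterisation itself, not implementation artifacts, and both are
covered by tests at exactly that scope.

## Disconnectome pipeline

Per subject: score fibers against the lesion mask, add each fiber's
score at its two endpoint voxels (fibers scoring 0 contribute nothing;
out-of-grid endpoints are skipped), smooth, then mask to GM — in that
order; mask-then-smooth is deliberately not offered. Endpoints outside
the GM mask still accumulate in the raw image and are only removed by
the final masking. GM masks may be thresholded from a probabilistic
template (default ≥ 0.5).

The per-voxel index stores *raw* (unsmoothed, unmasked) endpoint
contributions as a sparse integer matrix and smooths once at query
time. By linearity this is mathematically identical to storing
smoothed maps, at a fraction of the memory; the fast and direct paths
agree exactly (integer raw images, identical smoothing call), which the
equivalence tests assert at 1e-6 relative.

Scores are plain voxel counts: no fiber-length or lesion-volume
normalisation.

## Normative model and atrophy

Voxel-wise OLS of control GM on [1, age, sex, TIV] with mean-centered
covariates (centering affects conditioning only; stored means make
predictions centering-invariant). Requires ≥ 5 controls and a
full-rank design; a constant covariate column (e.g. single-sex
controls) raises an error naming the column. Voxels with zero variance
get slopes 0 and intercept = mean — no NaNs propagate.

Atrophy = predicted − observed, in GM-probability units by default
(positive = loss); a percent-of-predicted mode exists. Negative values
(tissue above expectation) are retained: clipping would bias
correlations and cohort means. Each timepoint's atrophy map uses the
subject's age at that scan. Longitudinal lesion change is the set
difference t2 \ t1 (shrinking lesions are logged, never negative);
atrophy change is the signed map difference.

## Statistics

Pearson r per in-mask voxel across subjects; two-sided p from the t
transform (n − 2 df). "Controlled for lesion volume" is implemented as
partial correlation: residualize both map stacks on [1, covariate] by
least squares and correlate residuals (n − 3 df). Voxels with zero
variance (or residual variance below 1e-10 of the original, i.e. maps
fully explained by the covariate) are flagged and reported as r = 0,
p = 1. BH-FDR is applied per analysis family over in-mask voxels;
q-values come from the standard step-up procedure and significance is
strict (q < alpha), matching the convention of counting only FDR
levels below 5%. Two-sided tests are the conservative default.

The default analysis mask keeps GM voxels where ≥ 90% of subjects have
a nonzero disconnection value and across-subject variance is positive.
On sparse synthetic tractograms this rule can select nothing; the
pipeline then falls back to the full GM mask (logged), where
uncovered voxels simply surface as flagged degenerate results.

Region summaries take the maximum r over significant voxels per atlas
label, with peak location and significant-voxel count; regions without
significant voxels are marked not-significant. Left/right merging is
delegated to the supplied label volume.

## Synthetic phantom and cohorts

The phantom is a 48³ grid at 2 mm (world origin at the volume center):
a spherical brain (radius 42 mm), K = 8 spherical GM regions (radius
8 mm) on an inner shell (28 mm, cube-vertex directions with seeded
jitter), WM = brain minus GM, and a GM probability template obtained
by smoothing the region labels (4 mm FWHM). Scale was chosen so a full
cohort analysis runs in about a minute on one CPU.

The tractogram connects all 15 pairs among regions 1–6 (200 fibers per
pair, quadratic-Bezier midpoint jitter sd 6 mm) so bundles crisscross
the deep WM the way a whole-brain template does; regions 7 and 8
receive no fibers and act as negative controls. Fiber endpoints are
sampled voxel centers inside their regions.

Lesions are unions of spheres centered at uniform WM voxels, radii
lognormal (median 3 mm, log-sd 0.25), counts Poisson. Per-patient
counts are Gamma–Poisson mixed via a severity multiplier
(Gamma(0.7), mean 1), reproducing the heavy-tailed lesion-load
distributions real cohorts show (load CV ≈ 1.2 rather than the pure
Poisson ≈ 0.45); the same multiplier scales new-lesion accrual so
active patients stay active. Baseline load is Poisson(8·severity)
(≈ 1–2 mL on the ≈ 360 mL phantom); follow-up spans 6 years at a
constant accrual rate of 2 lesions/year (Poisson(12·severity) new
lesions).

Control GM = template + β_age(age − 40) + β_sex·sex + β_tiv(TIV − 1500)
+ N(0, noise_sd) inside the brain, with age ~ U(20, 60), sex ~
Bernoulli(0.675) (female = 1), TIV ~ N(1500, 120) mL, β_age = −0.002/yr,
β_sex = −0.01, β_tiv = 5e-5/mL. Patients additionally lose
α · nd, where nd is the subject's disconnectome map (computed by the
same engine the analysis uses) normalized by the maximum over all
patients' baseline maps — so α is the peak injected GM loss in GM
units. Defaults: noise_sd = 0.02 and α = 0.2, calibrated so the
across-patient loss scale at the median affected voxel (≈ 0.05 in
normalized units) equals half the scan noise; at the strongest deep-GM
voxels this puts the disconnection–atrophy coupling near r ≈ 0.7–0.8,
the effect-size regime such studies report. "Truly affected" ground
truth marks GM voxels where ≥ 10% of patients receive normalized loss
> 0.02 (the coverage distribution is bimodal, so this selection is
insensitive to the exact cutoffs).

All randomness flows from a single master seed through named
`SeedSequence` substreams; identical seeds give bit-identical cohorts.
If a covariate draw happens to produce a single-sex cohort, one
subject's sex is flipped to keep the design full-rank (deterministic).

### What the generator does and does not emulate

It emulates: a common normalized space, lesion-load heterogeneity,
covariate-driven GM variation, disconnection-proportional GM loss, new
lesions with incremental connected loss, and fiber-free GM as negative
control. It does not emulate: registration/segmentation error, spatial
noise correlation, scanner effects, lesion masks that disagree with
the tractogram space, non-linear aging, or any direct (non-mediated)
lesion–atrophy pathway. Passing recovery tests therefore demonstrates
the *pipeline's* correctness and sensitivity under the stated
generative model, not performance on real MRI.

## Numerical choices

- Degenerate correlation voxels: r = 0, p = 1, flagged (never NaN).
- p-values floored at the smallest positive double so they stay in (0, 1].
- Disconnectome maps clamp at 0 (smoothing can produce −1e-17).
- The index matrix is int64; raw endpoint sums are exact integers, so
  fast-vs-direct equality is exact up to the shared smoothing call.
- NIfTI: masks uint8, scalar maps float32; gzip output is
  byte-deterministic, so re-running a pipeline from its saved config
  reproduces outputs bit-for-bit.

## Problem sizes

Default study conditions: 48³ grid, 3000-fiber template, 60 controls,
120 patients (both timepoints in longitudinal mode). A full
cross-sectional analysis (model fit, 120 disconnectomes + atrophy
maps, two correlation analyses, FDR, region table) takes a few seconds
after cohort generation (~15 s); the acceptance script completes in
about a minute on one CPU.

## Known limitations

- The voxel index covers only voxels some fiber passes through —
  lesions elsewhere correctly contribute nothing, but there is no
  warning when a lesion lies wholly outside fiber territory.
- Partial correlation supports a single control covariate, as in the
  analyses it implements.
- Surface-based (vertex-wise) analogues of the maps and statistics are
  out of scope.
- The plain-text tractogram format stores coordinates at 1e-6 mm
  precision; round-trips through it are not bit-exact (TRK is float32
  exact).
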