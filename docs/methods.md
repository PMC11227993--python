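# Methods

## The statistic

For a preprocessed BOLD voxel time series sampled every TR seconds, the
intrinsic neural timescale (INT) is

    INT = TR * sum_{k=1..m} rho_hat(k),

where `rho_hat(k)` is the biased (1/n-normalized) sample autocorrelation of
the mean-centred series at lag `k`, and `m` is the length of the initial
run of strictly positive autocorrelations: the window ends at the first lag
at which the ACF reaches or crosses zero (a value of exactly zero
terminates it).  If `rho_hat(1) <= 0` the INT is 0; it is never negative.
For a stationary AR(1) process with coefficient `phi` the population value
is `TR * phi / (1 - phi)`, which is what makes an AR(1) cohort a usable
ground truth.

Estimator choices, each exposed as an option:

* **Biased vs unbiased ACF.** The 1/n normalization damps long-lag
  estimates on short series (160 volumes here), the standard choice for
  timescale work; the unbiased 1/(n-k) form can explode near `k = n`.
* **Lag 0.** Excluded by default: including it adds exactly `TR` to every
  voxel, which shifts maps by a constant and leaves every group contrast
  and correlation unchanged.  `include_lag0=True` restores it.
* **Area rule.** Left Riemann sum of unit-width ACF bars (default);
  a trapezoidal variant integrates the ACF polyline instead.
* **Maximum lag** defaults to half the series length; the positive window
  terminates far earlier in practice.
* **Degenerate voxels** (exactly constant or non-finite series) are flagged
  undefined — NaN in the map, excluded from every mean — never zero-filled.

Maps are smoothed with a mask-aware Gaussian kernel (default FWHM 8 mm,
`sigma_vox = FWHM / (voxel_size * sqrt(8 ln 2))` per axis): both the
zero-filled values and the binary mask are convolved and the ratio taken,
so undefined and out-of-brain voxels do not dilute in-mask values and a
constant map is exactly invariant.

## Preprocessing

Fixed order: discard the first 5 volumes, regress confounds, band-pass.

* **Confound regression**: per-voxel OLS residuals against an intercept
  plus six motion parameters and the WM/CSF signals (a Friston 24-motion
  expansion is available; 6 is the default since nothing identifies the
  richer model as the study's choice).  Columns are used on their native
  scales; residuals are orthogonal to every regressor by construction.
* **Band-pass**: zero-phase (forward-backward) Butterworth, order 2 per
  pass, 0.01-0.1 Hz, odd-reflection padding.  The filter design is a
  package choice — only the band is fixed by the study description — and
  order 2 keeps the pass band monotone on 160-point series.  The analytic
  two-pass gain is 0.995 at 0.05 Hz and < 0.001 at 0.2 Hz (TR 2.2 s).
* **Motion QC** excludes subjects, not frames: mean displacement > 3 mm.
  "Head motion" is read as the mean realignment displacement (a max-FD
  variant is available by option).  Framewise displacement is Power-style:
  sum of absolute backward differences, rotations converted to arc length
  on a 50 mm sphere.

## Group inference

* **Two-sample tests** use the pooled-variance Student t, identified by the
  reported degrees of freedom (df = n1 + n2 - 2), with eta^2 =
  t^2/(t^2+df).
* **Correlations** report Pearson r with a pairs-bootstrap two-tailed
  sign-crossing p (default 10 000 resamples), floored at 1/n_boot.  The
  percentile construction is a package choice; the study states only that
  a non-parametric bootstrap with 10 000 samples was used.  A Shapiro-Wilk
  screen is computed to justify the non-parametric reporting; it does not
  change what is computed.
* **Voxelwise comparison** fits per voxel the linear model
  [intercept, group, age, sex] and takes the group-contrast t.  Cluster
  correction is by permutation rather than random-field theory: supra-
  threshold voxels (|t| above the two-tailed p < 0.001 critical value —
  a conventional forming threshold, configurable) are labelled by face
  connectivity (6; 18/26 available), and each observed cluster's p_FWE is
  `(1 + #{permutation max cluster size >= observed}) / (1 + n_perm)` under
  group-label exchange with covariates held fixed.  Default n_perm = 1000
  at toy scale.

## Mediation

OLS path estimates (a from M~X; b, c' from Y~X+M; c from Y~X; ab = a*b) on
native scales without covariates (a covariate hook exists but is not the
default).  The decomposition c = c' + ab is exact for OLS on a common
sample and is asserted on every fit.  Inference on ab resamples subjects
with replacement (default 10 000), with a percentile 2.5/97.5 interval and
a two-tailed sign-crossing p floored at 1/n_boot; the bootstrap is
vectorized through closed-form 3x3 normal equations, so identical seeds
give identical intervals.  Mediation models are fitted only when all three
pairwise correlations are individually significant (the precondition
screen), and two-tailed p-values are used throughout; models that fail the
screen are reported as "not evaluated" with the failing pair named.  The
model suite per focal ROI covers both orientations of the
local-INT/DMN-INT/MMSE triad, the anatomical chain GMV -> local INT ->
DMN INT (and -> MMSE), the reversed sensitivity model local INT -> GMV ->
DMN INT, and six control-network substitutions for the DMN, with
Bonferroni correction over focal ROIs.

## The synthetic cohort

Every voxel is a stationary AR(1) draw; coefficients are set per
(parcel, group).  Defaults (TR 2.2 s, 160 retained volumes + 5 lead-in,
20x20x12 grid at 4 mm — the acquisition scale of the emulated study, kept
desk-size):

| parcel | phi CN | phi AD | tau CN (s) | tau AD (s) |
|---|---|---|---|---|
| AG | 0.80 | 0.50 | 8.8 | 2.2 |
| SMG | 0.75 | 0.60 | 6.6 | 3.3 |
| DMN-core | 0.70 | 0.60 | 5.1 | 3.3 |
| six control networks | 0.50 | 0.50 | 2.2 | 2.2 |

The AG gap (0.8 vs 0.5) is the planted focal deficit; control networks are
group-neutral.  No empirical INT range is published for the emulated data,
so these values are chosen for statistical power at n = 30 per group, not
to match unprinted magnitudes.

Subject-level generative timescales carry the mediation chain: the AG
timescale varies between subjects (sd 1.5 s), the DMN-core timescale
follows it with slope `a_gen = 0.8` (residual sd 0.5 s), AG grey-matter
volume follows the AG timescale with unit slope (noise sd 0.5), and MMSE =
26 + 0.6 * (DMN timescale deviation) + c'_gen * (AG timescale deviation) +
noise (sd 1), rounded and clamped to [0, 30].  With `cprime_gen = 0` the
chain GMV -> AG INT -> DMN INT -> MMSE is a complete mediation.  MMSE and
GMV are generated from the *true* timescales, not the estimates, so
estimator noise attenuates but cannot bias recovery.  The digit-span score
is coupled to the DMN timescale (loading 0.7); the other six battery tests
are independent noise, giving the component screen exactly one true
positive.  Confounds are slow sinusoidal motion drifts plus low-pass
filtered WM/CSF noise, mixed into in-brain voxels with random per-voxel
loadings (amplitudes 0.5 of the AR noise sd); background voxels are white
noise.  All randomness descends from the cohort seed; per-subject streams
come from CRC-32 hashing of the subject id, so single subjects regenerate
lazily and identically.

What the generator does **not** emulate: haemodynamic response shape,
spatial autocorrelation of noise (beyond optional smoothing),
non-stationarity, realistic motion artefact structure, T1 anatomy (GMV is
a scalar per ROI — the VBM stage is out of scope), and scanner drift
beyond the injected confounds.  Passing recovery tests therefore shows the
estimators and inference machinery are correct and calibrated under the
stated generative model, not that the pipeline is robust to everything
real rsfMRI contains.

## Numerical and design notes

* ACFs are computed by FFT convolution; equality with direct summation is
  asserted to 1e-10 per series in the acceptance suite.
* The voxelwise GLM with covariates orthogonal to both the contrast and
  the data reproduces the unadjusted two-sample t exactly up to the df
  factor `sqrt((n-4)/(n-2))` (the covariates consume two df); the test
  asserts that exact relation.
* Sphere ROIs use voxel centres with an inclusive boundary
  (distance <= radius), so a 4 mm sphere on the 4 mm grid holds 7 voxels;
  a sphere is never empty (nearest-voxel fallback).  In the pipeline, ROI
  centres default to the peaks of significant clusters, mirroring the
  peak-coordinate flow of the emulated analysis.  At toy scale, tests of
  the planted mediation chain use the AG parcel mean as the local INT —
  the parcel *is* the region here, and the 48-voxel average keeps
  estimator noise from masking the planted asymmetry.
* Mediation in the pipeline runs on the AD group by default (the emulated
  analysis does); the suite itself is group-agnostic and the planted-chain
  acceptance check runs it on the full cohort table, where the chain also
  holds.
* Problem sizes in the test and acceptance suites are package choices:
  cohorts of 30+30 (15+15 for null-calibration replicates, 8+8 for
  byte-determinism runs), 1000 bootstrap and 500 permutation resamples in
  replicate loops, 10 000 by default in single production runs.

## Known limitations

* Band-pass filtering reshapes the ACF, so estimated INT is a compressed,
  nonlinear (but monotone) function of the generative timescale; recovery
  tests assert ordering, correlation and mediation structure, not absolute
  tau values.
* The permutation test assumes group exchangeability given the design;
  covariates are held fixed rather than re-fitted (no Freedman-Lane
  refinement), adequate here because the synthetic covariates are
  independent of group.
* The bootstrap product test for ab is conservative near the null, which
  the calibration check treats as acceptable (<= 0.08 at nominal 0.05).
* Only axis-aligned (diagonal-affine) NIfTI geometries are supported.
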