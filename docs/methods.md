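# Methods

## Scope and design

The package reproduces, at desk scale, the logic of a two-session
test–retest study of single-subject task-fMRI activation: a factorial
sweep of processing methods (motion correction × smoothing × regression
× thresholding) applied to every run of every subject and session,
followed by cluster extraction, cross-session cluster matching and
three reproducibility metrics (PDAV, DCM, DSC) compared across methods.
Real scanner data is replaced by a synthetic cohort with known ground
truth so that every stage has a closed-form or simulation-verifiable
answer.

The library API is the primary surface; `examples/` holds one narrative
script per capability and the `boldrepro` CLI is a thin wrapper for the
simulate / run / report loop.

## Task paradigms

The five-run battery is hard-coded from its block structure: volume
totals 76, 173, 88, 184, 238; TR 2.5 s except the two overt-speech runs,
which are sparse-sampled at an effective TR of 5 s. Sparse acquisition
is modelled simply as a block design with TR = 5 s; acquisition gaps and
their consequences (no signal during silent periods, different noise
spectra) are not simulated. Task regressors are the block boxcar
convolved on a 0.1 s grid with a canonical double-gamma HRF (response
peak ~5 s, undershoot ~16 s, 6:1 peak-to-undershoot ratio), sampled at
the TR and normalized to unit peak so that regression coefficients read
in signal units. Generation and fitting share the same regressor, so
amplitude recovery is exact in the noiseless limit by construction —
tests exploit this for calibration, and it means the tests say nothing
about HRF misspecification on real data.

## Synthetic cohort

Defaults (one choice, made once): 4 mm isotropic voxels on a 32×32×24
grid (a smaller grid than a real acquisition, for test speed; the shape
is configurable), an analytic ellipsoid brain mask with semi-axes at
45% of each grid extent, baseline 100, noise SD 1 (temporal SNR 100),
AR(1) coefficient 0.3, noise smoothness 6 mm FWHM, between-session
center jitter SD 2 mm and multiplicative amplitude jitter SD 10%.
Ground-truth activation is a hard sphere (default radius 10 mm,
amplitude 2% signal change) with a raised-cosine roll-off one voxel
wide, giving clusters stable but non-trivial boundaries.

Noise order of operations (fixed, so tests can build oracles): draw
white Gaussian noise → smooth spatially → AR(1)-filter in time → scale
the whole field so its in-mask SD equals `noise_sd`. Each voxel's
series then has the requested lag-1 autocorrelation and the field the
requested smoothness. Optional rigid head motion is applied per volume
by trilinear resampling of the clean signal before noise is added.
Randomness derives from `numpy` SeedSequences spawned per (subject,
session, run), so subjects and sessions have disjoint streams and any
member can be regenerated independently. An `identical_sessions` switch
makes session 2 reuse session 1's stream with no jitter — the
bit-identical scan-rescan used to verify the end-to-end ideal (every
matched pair at PDAV 0, DCM 0, DSC 1).

Not emulated: physiological noise, susceptibility distortion, slice
timing, scanner drift beyond the polynomial-removable kind, and — most
importantly — anatomical inter-session misalignment: both sessions live
on one shared grid, so the cross-session registration step of a real
study (and its errors) is out of scope, and DSC is computed on the
shared grid directly. Passing tests therefore demonstrate the internal
consistency of the pipeline machinery, not robustness to real-data
artifacts.

## Preprocessing

Rigid motion correction registers every volume to volume 0 by
minimizing the sum-of-squares intensity difference over the six rigid
parameters (rotations in degrees about the grid center, then
translations in mm). The search is Powell's method started from rest
(plus a warm start from the previous volume when it exceeds 0.05
parameter units), with the cost evaluated on a stride-2 decimated grid
and one full-resolution polishing iteration; parameter tolerance 1e-3.
Reported parameters are the estimated *head motion* (the negated
correcting transform — exact for translations, first-order for combined
rotations). After either arm (`NoMoCo` or `Rigid3D`) the initial
volume is dropped from the run. The 2D+3D and affine arms of the
original four-way menu are declared in the menu but not implemented;
the stage is a function from run to (run, parameters), so they can be
plugged in.

Framewise displacement is the Power convention: sum of absolute
backward differences of the six parameters with rotations converted to
arc length on a 50 mm sphere. The convention is an assumption — the
0.2/0.5 mm censoring thresholds match the values in common use for
exactly this formula.

Masked smoothing computes `smooth(data·mask)/smooth(mask)` and zeroes
the outside, so nothing leaks across the mask edge and constants are
preserved exactly inside; FWHM 0 is the identity inside the mask.

## Regression

Every design contains a Legendre polynomial baseline (order 1 for runs
under 150 printed volumes, order 2 otherwise — judged on the printed,
pre-removal count, since the rule refers to run length), the task
regressors of all of the run's conditions fitted jointly, and
variant-specific extras. `Cen2`/`Cen5` censor volumes with FD above
0.2/0.5 mm by row deletion. `MPC` appends the six motion-parameter
series (demeaned; flat columns dropped to protect the design's rank);
the censoring and covariate variants always take their parameters from
the rigid 3D estimate, whatever the motion arm of the pipeline, since
the parameters are an estimate of true motion rather than a property of
the chosen correction. Degrees of freedom are retained volumes minus
design rank.

`REML` is a single-iteration Cochrane–Orcutt AR(1) prewhitening: a
first OLS pass estimates each voxel's lag-1 residual autocorrelation;
estimates within sampling noise of zero (|ρ| ≤ 2/√T) are treated as
white, the rest are binned on a 0.01 grid and each bin is whitened
(y*₀ = √(1−ρ²)·y₀, y*ₜ = yₜ − ρyₜ₋₁) and refit. The significance gate
is what keeps the white-noise case equal to OLS to within estimation
noise; an ARMA(1,1) model and true restricted-likelihood iteration are
deliberately out of scope — AR(1) captures the dominant term the
generator produces.

## Thresholding

All tests are one-sided in the positive-t direction (the study's
activations are task-positive; sidedness is an assumption and is
flagged here). Bonferroni: voxel active iff p·N < .01, strict. FDR:
Benjamini–Hochberg adjusted q < 1e-5, strict. AMPLE: t as a percentage
of the maximum t over each of five sectors (frontal, occipital,
parietal, temporal, other — for the synthetic ellipsoid, four
quadrant sectors plus a central core standing in for lobes), active
iff > 60%, strict; a sector with nonpositive maximum yields no
activation and a warning.

Cluster-extent (`Clst`): residual smoothness is estimated per axis from
the lag-1 spatial autocorrelation of variance-normalized residuals
(Gaussian-ACF estimator, reported as the FWHM of the kernel that would
produce it on white noise); the null distribution of the largest
6-connected cluster above the one-sided p < 1e-4 voxel threshold is
simulated by Monte Carlo with an isotropic Gaussian field at the
geometric-mean FWHM, and k(α=.01) is the smallest extent whose
exceedance frequency is ≤ α. Simplifications: Gaussian ACF (no
long-tail mixed ACF), isotropic null, mean/variance-normalized field
inside the mask. The null and the data share 6-face connectivity, so
both are treated identically. In the sweep, null tables are cached by
smoothness rounded to 0.5 mm, since k varies slowly with FWHM.

## Clusters, matching, metrics

Clusters are 6-connected supra-threshold components of at least 12
voxels (768 μl at 4 mm voxels) with a t-weighted center of mass
Σtᵢxᵢ/Σtᵢ in mm. ROI masks per activation type take voxels active in
at least 10% (inclusive) of all maps of that type across pipelines,
subjects and sessions; a cluster enters the analysis iff the voxel
containing its center of mass (floor of the fractional voxel
coordinate) is in the ROI. Matching: for each test-session cluster
independently, the closest retest cluster within 10 mm (inclusive);
many-to-one matches are allowed. PDAV, DCM and DSC are computed per
matched pair; PDAV is bounded by [0, 200], DSC by [0, 1].

## Statistics across methods

One matched cluster pair is one observation. For each stage, activation
map and unordered method pair, values are pooled across subjects and
the other three stages and compared with a pooled-variance unpaired t
test; raw p-values are Bonferroni-multiplied by (number of method
pairs) × (number of activation maps), capped at 1. A method is
"significantly better" when the corrected p is below .05 and its mean
is on the favorable side (lower PDAV/DCM, higher DSC); the stage
summary reports per method the percentage of its comparisons won.
Cohen's d uses pooled variance ((n₁−1)s₁² + (n₂−1)s₂²)/(n₁+n₂) by
convention here, with the textbook n₁+n₂−2 denominator available as a
keyword. Kruskal–Wallis (tie-corrected, χ² p with k−1 dof) screens
whether a stage's distributions differ at all; identical constant
groups return (H, p) = (0, 1) by convention.

## Numerical and degenerate-input choices

- Zero residual variance yields t = 0 rather than ±∞ (noiseless runs
  are analyzed through their betas, not their t-maps).
- AR(1) estimates at |ρ| ≥ 1 are clipped to 0.99 with a warning.
- Empty activation maps, empty cluster lists and empty match sets are
  valid outputs, not errors; `pdav` and `dsc` reject the all-zero /
  all-empty pairs that the matching stage cannot produce.
- The sweep isolates failures per analysis unit into a machine-readable
  error table and never aborts.
- Re-running a study with the same config and seed reproduces the
  records table exactly.

## Problem sizes

The test suite and the acceptance script run reduced designs chosen as
the smallest sizes that still exercise every code path: one or two
subjects, run1 (76 volumes), 2×2×1×1 factorials, 1,000 Monte-Carlo
iterations for cluster-size tables, and 100–200 voxel toy fits for
oracle comparisons. The full 400-pipeline, 10-subject bookkeeping is
verified arithmetically (64,000 planned analyses) without executing the
sweep; nothing in the code caps the sizes a user can request.

## Known limitations

- Only `NoMoCo` and `Rigid3D` motion arms are executable.
- The synthetic region atlas is a geometric stand-in; anatomical
  labeling of clusters is out of scope.
- Between-session anatomical alignment (and MNI-space ROI construction)
  is collapsed onto a shared grid.
- The matching rule can pair one retest cluster with several test
  clusters; this mirrors the stated rule and is left as-is.
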