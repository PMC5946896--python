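# Methods

This note documents the models, defaults and numerical choices behind
`semdecode`, and what the synthetic-data tests do and do not establish
about real data.

## The generative model

A dataset is one beta volume per (subject, task, language, run, concept)
on a common voxel grid (default 20×20×20 voxels at 3 mm for desk-scale
runs; `VolumeGeometry.mni152_3mm()` gives the full 61×73×61 standard-space
grid).  Each subject's noise-free signal is a sum over *effect regions*;
within a region, every concept has a pattern drawn i.i.d. N(0, 1) per
voxel and scaled by the region amplitude.  The sharing mode decides which
condition cells reuse the same draw:

| sharing            | same pattern across                  | transfers under                     |
|--------------------|--------------------------------------|-------------------------------------|
| `shared_semantic`  | both languages and the listed tasks  | cross-language and cross-modality   |
| `language_specific`| listed tasks, within one language    | cross-modality within a language    |
| `modality_specific`| both languages, within one task      | cross-language within a task        |
| `none`             | — (no concept signal)                | nothing                             |

Run-level i.i.d. Gaussian noise (sd `noise_sd`, default 1.0) is added to
every beta; `amplitude / noise_sd` is therefore the per-voxel
contrast-to-noise ratio.  Optionally the noise can be spatially smoothed
(`noise_smooth_fwhm_mm`) and rescaled to unit variance, giving spatially
autocorrelated noise; this is off by default because the decoding
contracts are simplest to verify under i.i.d. noise.

All randomness flows from one seed through three independent streams
(concept patterns, beta noise, events/time-series noise), so (a)
identical configs are bit-identical, and (b) the directly generated beta
dataset and the simulated raw time series share the same underlying
concept patterns — the basis of every parameter-recovery test.

### Event timing and raw time series

Runs hold `n_concepts × presentations_per_run` trials (default 10 × 6 =
60): 1 s stimulus, then an inter-trial interval drawn from the 1.0–5.2 s
lattice in 0.3 s steps with exponentially decaying ("pseudologarithmic")
weights tuned to a 2.6 s mean.  Runs are 143 scans of TR 2 s (the
analyzed length after discarding dummy scans at acquisition); a config
whose trials cannot fit the run is rejected rather than truncated.
Behavioural accuracy is Bernoulli per trial (default 1.0 — the emulated
task is near-ceiling and no error rates are published, so this is a free
parameter that merely exercises the incorrect-trial exclusion path).

The raw series of a run is `X @ amplitudes + drift + noise`: `X` holds
the HRF-convolved per-concept boxcars (the same convolution routine the
GLM uses, so noise-free estimation is exact), the drift is a random
combination of the run's sub-cutoff DCT basis vectors scaled to rms
`drift_sd` per voxel (i.e. deliberately *inside* the span the high-pass
removes), and the noise is white Gaussian.

## First-level GLM

Design per run: one canonical-HRF regressor per concept built from that
concept's correct trials, the temporal derivatives of those regressors,
optional 6 motion columns, the DCT high-pass set, and an intercept.
Estimation is voxel-wise OLS; only the canonical concept betas are kept.

* **HRF** — double-gamma difference: gamma(shape 6, scale 1) −
  (1/6)·gamma(shape 16, scale 1), 32 s window, rescaled to unit peak.
  The response is 0 at t = 0 and peaks at ≈ 5 s.  These are the de-facto
  standard parameters in the SPM software family; the emulated study
  does not state its HRF parameters.
* **High-pass** — cutoff 128 s, implemented as DCT regressors in the
  design rather than pre-filtering; for OLS the two are identical and
  the in-design form keeps betas manifestly invariant to any drift in
  the DCT span.  The number of columns is the count of frequencies
  k/(2T) strictly below 1/128 (e.g. 4 for a 304 s run).
* **Convolution grid** — regressors are built on a TR/16 grid and
  sampled at scan onsets, so sub-TR event onsets are honoured.
* **Degenerate concepts** — if every trial of a concept is excluded,
  its column is all zeros; it is flagged unestimable, skipped during
  estimation, and its betas are NaN (zeros after dataset assembly, with
  a note).  Chance level downstream always uses the full concept count;
  this is conservative and keeps class counts constant across folds.
* **Rank checks** — a rank-deficient design is rejected with the
  offending column names (from the QR diagonal), rather than silently
  pseudo-inverted.

### Correlated estimation noise (why "matched noise" is subtle)

OLS concept betas within a run have covariance σ²(XᵀX)⁻¹ (concept
block): concepts presented close together in time get *correlated*
estimates, coherently at every voxel.  Empirically this matters a lot
for decoding — at the emulated event density, i.i.d. beta noise at the
matched per-voxel level yields accuracies ~15–20 percentage points
higher than the GLM route.  The pipeline-consistency test therefore
matches the full per-run covariance (Cholesky of the concept block of
σ²(XᵀX)⁻¹) when generating the reference betas, and at that matching the
two routes agree to well under 1 percentage point.  Users comparing
simulated to estimated patterns should match covariance, not just
variance.

## Decoding

* **Classifier** — k-NN, default k=1 with Euclidean distance.  The
  emulated analysis does not state k or the metric (and reports that
  other classifiers behave similarly); 1-NN on z-scored patterns is the
  simplest member of the family.  Features are z-scored per voxel with
  statistics fitted on the training folds only (no test leakage);
  because the centering cancels in differences, z-scoring is exactly a
  per-voxel inverse-sd weighting of the distance.  Ties are
  deterministic: equal distances resolve by training order (stable
  sort), tied votes by the smallest concept label.
* **Schemes** — cross-language: within one task, train on 4 of 5 runs
  of one language, test the held-out run of the other; 5 folds; the
  mirrored direction's map is averaged in.  Cross-modality: train task A
  in L1, test task B in L2 (and mirrored); run-wise folds are kept by
  default for comparability (an all-runs variant is a flag).
  Within-language schemes are constructible but carry a
  `lexically_confounded` flag: within one language, semantic and lexical
  overlap are indistinguishable by design.
* **Searchlight** — radius 3 voxels (123 offsets).  Spheres are
  truncated at mask edges (in-mask voxels only); centres with fewer than
  `min_voxels` (default 10) in-mask voxels are undefined (NaN), never 0.
  The implementation assembles squared Euclidean distances from
  sphere-sums of squares and cross-products; each sphere sum is computed
  by cumulative sums along x over the sphere's run-length decomposition,
  which makes the whole map a few dense array operations per fold.
  Accumulation is in single precision — only the argmin over training
  patterns matters, and the brute-force oracle test confirms exact
  agreement on continuous data.  Non-Euclidean metrics take a per-centre
  reference path.
* **Smoothing** — applied *after* decoding (8 mm FWHM default at the
  group stage), mask-aware: the map and the mask indicator are smoothed
  separately and divided, so edge values are renormalized weighted
  averages and undefined voxels do not bleed in.  Directions are
  averaged before smoothing.

## Group statistics

One-sample t against chance per voxel (one-sided: only above-chance
decoding is hypothesised); z-equivalents by upper-tail probability
matching, capped at the z for p = 1e-16.  Zero-variance voxels are
undefined, not infinite.  Clusters form under 26-connectivity (6/18
available).

Cluster-extent correction is a **sign-flip permutation test**: under the
null the per-subject deviations from chance are symmetric, so each
permutation flips every subject's deviation map with probability 1/2,
recomputes the t-map, and records the maximal cluster extent; corrected
p = (1 + #{null ≥ extent}) / (1 + n_perm).  This replaces the parametric
random-field cluster correction of the emulated analysis: accuracy maps
are bounded, non-Gaussian quantities, and the permutation test is
distribution-free with the same family-wise error contract (its
calibration is verified empirically in the suite).  Fewer than 5
subjects triggers a warning (sign-flip space < 32).  Because s² enters
through Σx² − n·m̄², which is flip-invariant, all permutation t-maps come
from a single matrix product.

## ROI statistics

The five built-in ROIs are the standard-space semantic-network
coordinates for first-language written-word processing: left inferior
frontal gyrus (−45, 23, 12), left middle temporal gyrus (−56, −44, 4),
cerebellum (20, −78, −35), left superior motor area (−3, 16, 53), left
middle frontal gyrus (−27, 13, 52).  Only the peak coordinates of the
source study are public, so the default extent is a transparent stand-in:
an 8 mm-radius sphere (configurable; explicit NIfTI masks accepted).

An ROI is decoded as one pooled feature vector (no searchlight) with the
same scheme and classifier settings as the whole-brain analysis.  The
group null follows the permutation + bootstrap recipe: concept labels
are permuted independently within every run the scheme touches
(permutations sampled uniformly with replacement — the full group is
astronomically large), giving P = 100 chance accuracies per subject;
drawing one per subject and averaging, B = 10000 times, yields the
group-level null; p = (1 + #{null ≥ observed}) / (1 + B), never exactly
zero.  Across ROIs, Benjamini–Hochberg at q = 0.05.

## Problem sizes in the test suite

The suite verifies calibration and recovery at desk scale: 20³ grids and
10 subjects for the parameter-recovery replicates, 8³ grids with 4
concepts for the 200-replicate family-wise-error calibration, and reduced
permutation counts (P = 24, B = 300) for the p-uniformity check.  These
sizes keep the full suite around ten minutes on one core while
leaving every statistical check non-trivial (the acceptance numbers are
recomputed at the full P = 100 / B = 10000).

## What the simulations do not show

The generator emulates the *design*, not the physiology: no hemodynamic
nonlinearity, no physiological or motion noise, no EPI distortion, no
per-image stimulus structure (the two-images-per-concept counterbalancing
of the emulated study is representable only as nuisance components in a
`modality_specific` region), and spatially white noise by default where
real BOLD noise is autocorrelated.  Passing recovery tests therefore
demonstrates that the *analysis chain* is correct and calibrated — not
that it would detect signals of any particular strength in real data.
Real-data Z-scores and cluster tables of the emulated study are not
reproduction targets: the underlying data were never deposited.
Preprocessing (motion correction, slice timing, spatial normalization)
is out of scope; inputs are assumed to be in a common voxel space.
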