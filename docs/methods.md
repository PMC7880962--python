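# Methods

This note documents the models implemented in `radbatch`, the conventions
chosen where several were defensible, and what the synthetic study
conditions do and do not establish about real CT data.

## Digital phantom and acquisition model

The phantom is a simplified digital analogue of a tissue-characterization
insert: up to 13 parallel cylindrical rods (one central, a ring of 4, a ring
of 8; default diameter 6 mm, height 10 mm) in an air background of
−1000 HU, sampled on a fine ground-truth grid (default 0.35 mm, required
≤ 0.5 mm). Rod mean densities span lung surrogates (−690, −440 HU), soft
tissues (adipose −90, breast −35, water 0, solid water 5, brain 30, liver
90) and bone surrogates (210–1150 HU). Real phantom rods are nearly
homogeneous yet their texture features still vary between protocols; as a
stand-in for the unmodelled sub-voxel structure each rod carries a smooth
Gaussian random texture field (white noise filtered to a correlation length
of 1.5 mm, default SD 15 HU). The texture scale/SD are proxies, not
calibrated to any physical rod.

An acquisition applies, in order:

1. **Partial volume in z** — a uniform moving average over the slice
   thickness (window rounded to ground-truth voxels).
2. **Grid resampling** — linear interpolation onto
   (pixel_size, pixel_size, slice_spacing); output size covers the input
   extent (`ceil(extent/spacing)`), origin preserved, voxel centers at
   `origin + index·spacing`.
3. **Reconstruction kernel** — vendors do not publish kernel PSFs, so
   kernels A–E form a monotone sharpness ladder: A, B, C are Gaussian PSFs
   with σ = 1.2, 0.8, 0.5 mm; D, E are unsharp masking (gain 0.5, 1.0 over
   a 0.5 mm Gaussian). This reproduces the qualitative pattern that
   adjacent kernels (A–B) agree and distant ones (A–D) diverge.
4. **Voltage** — a global linear contrast factor
   `c(kV) = 1 + 0.5·(120/kV − 1)`, monotone in 1/kV and equal to 1 at the
   120 kV reference. No beam hardening; this is only meant to make low-kV
   (90) protocols diverge from the 120–140 kV range.
5. **Noise** — additive white Gaussian noise with
   `SD = 10 HU · sqrt(200/mAs)`; `current = inf` disables it (used by the
   deterministic tests).

All stages except noise are deterministic; every generator is reproducible
from its seed. Because stages 1–3 are linear shift-invariant and stage 4 is
linear, ROI means are conserved away from boundaries; "away" must clear the
full PSF footprint (one voxel + half the averaging window + ~4σ of the
kernel), since the −1000 HU background otherwise leaks tens of HU into a
100 HU rod.

Rod masks are rasterized analytically (cylinder equation at voxel centers)
on whatever grid a volume lives on, so the same physical VOI is reused
across protocols without mask interpolation — mirroring a study design in
which the phantom does not move between scans.

Not modelled: sinogram/FBP physics, dose, helical pitch, scatter, beam
hardening, metal artifacts.

## Preprocessing and the 93 features

Images are resampled to isotropic 1 mm voxels with an interpolating cubic
B-spline (scipy `map_coordinates` with prefiltering — exact at grid nodes,
reproduces constants and linear ramps); masks use nearest neighbor and are
re-thresholded at 0.5 to stay binary. Intensities in the ROI are
discretized to fixed 50 HU bins anchored on the absolute HU grid
(`level = floor(v/w) − floor(min/w) + 1`), which makes the levels invariant
to shifts by whole bins and the bin count independent of sub-bin offsets.

The feature set is the classic 93-feature battery: 18 first-order
statistics plus five 3D texture families — GLCM (24), GLDM (14), GLRLM
(16), GLSZM (16), NGTDM (5) — using distance 1 and the 13 unique 3D
directions. Conventions follow the widely used open-source extractors:

* GLCM and GLRLM are computed per direction (GLCM symmetrized and
  normalized per direction) and the *features* are averaged over
  directions; directions with no voxel pair are dropped.
* GLSZM zones and GLDM dependencies use 26-connectivity; GLDM counts a
  neighbor as dependent when |Δlevel| ≤ α (default 0) and stores
  dependence + 1 as the column index. NGTDM excludes voxels with no in-ROI
  neighbor.
* Population moments throughout (variance with 1/n, kurtosis without the
  −3 correction); first-order entropy/uniformity use the 50 HU histogram,
  energy/RMS use raw HU.
* Degenerate (uniform) ROIs take the standard guards: entropy 0,
  uniformity 1, GLCM correlation and MCC 1, NGTDM coarseness capped at
  1e6; every feature is always finite.

The texture matrices are verified against brute-force enumeration oracles
(exact integer counts) and the full 93-vector against an independent
loop-based reimplementation of every formula, kept in the test suite.

## Robustness screening

For each feature and protocol pair, ICC(2,1) — two-way random effects,
absolute agreement, single measurement — is computed across the phantom
materials as subjects. Absolute agreement is deliberate: for harmonization
screening, a protocol that shifts every value by a constant must count as
non-reproducible, which consistency-type ICCs would hide. A feature is
robust when ICC > 0.8; an acquisition variable is a batch when any of its
pairs has strictly fewer than 80% robust features.

Robust proportions are compared with the chi-square test with Yates
continuity correction (the algebraic equivalent of the continuity-corrected
two-proportion z test; the uncorrected z is available behind a flag) —
this is the variant whose BH-adjusted p-values reproduce the published
worked example exactly. The BH family is the set of comparisons within one
variability factor and correction method.

## ComBat

Parametric empirical-Bayes ComBat with no covariate matrix: features are
standardized by the grand mean (batch-size-weighted mean of batch means)
and the pooled within-batch SD; per-batch location γ and squared scale δ²
estimates are shrunk with a normal / inverse-gamma prior, hyperparameters
by method of moments, and the coupled posterior means iterated to 1e-6
(max 1000 iterations; the reference R implementation stops at 1e-4, with
which corrected values agree to ~1e-5). Constant features cannot be
standardized; they are excluded and passed through unchanged. Covariates
are omitted on purpose — the downstream validation is unsupervised and
conditioning on class labels would leak them into the correction. A
nonparametric mode (Monte-Carlo empirical prior over the other features'
raw estimates) is available behind a flag; the parametric mode is the
default.

## SVD correction

Features are z-scored (so the decomposition reflects correlation, not raw
scale — the 93 features span wildly different units), decomposed by SVD,
and every component's score vector is tested for association with each
batch variable by one-way ANOVA. Components with p < 0.001 for any batch
variable are zeroed before reconstruction. With nothing removed the
transform is the identity to float precision; removing everything leaves
each feature at its grand mean. Combined batches (e.g. thickness × kernel)
use Cartesian-product labels. The correction is refit per dataset.

## Clustering purity

K-means (k = 2: two phantom materials, or two primary tumor types) with
random initialization is run 1000 times on z-scored features; each run's
purity (fraction of samples in their cluster's majority class) is rounded
to 4 decimals, and the reported value is the highest purity whose frequency
across runs strictly exceeds 20% — a mode-seeking rule that ignores rare
lucky initializations. When no single rounded value is that frequent (the
restart distribution can be diffuse over many near-tied partitions,
especially after harmonization), the rule falls back to its cumulative
form: the highest purity level attained or exceeded in more than 20% of
runs. Both readings coincide with the plain maximum at threshold 0.

## Synthetic clinical cohort

The two-class cohort generator draws feature vectors from exactly the
location-scale model ComBat assumes: `y = baseline + class effect +
batch shift + batch scale · N(0, noise SD)`, so fitted batch parameters can
be checked against ground truth. The default cohort reproduces the
published clinical arm's structure: 97 lesions (52 + 45) over two scanner
batches with the published cross-tabulation (28/23 and 24/22), a ~0.8 SD
class effect on 30 of 93 features, and a second batch with ~1 SD random
shifts and 1.6× noise scale — a batch effect strong enough to partially
mask the class signal, as scanner effects do.

## What the synthetic conditions show — and what they don't

Passing tests establish that the pipeline's statistics are implemented
correctly (oracle equivalence, parameter recovery, exact reproduction of
the published worked-example arithmetic) and that the study's qualitative
findings emerge from the simulated physics: isotropic resampling raises the
robust-feature percentage for voxel-size factors; kernel and thickness act
as batches; ComBat improves two-class clustering purity on confounded
tables. They do not calibrate the simulator to any scanner: absolute ICC
percentages and purity values from the simulation differ from those of
physical phantom scans (e.g. the digital brain/liver rods separate at
purity 1.0 even before correction, because real inter-protocol variation
and intra-rod structure are richer than the synthetic texture model).

## Problem sizes and numerics

Default study: 13 materials; one-variable-at-a-time sweeps around a
120 kV / 200 mAs / 2 mm / 1 mm / 0.78 mm / kernel-A baseline (pixel 0.39,
0.78, 1.0 mm; spacing 1–5 mm; thickness 2, 3, 5 mm; kernels A–E; 90–140 kV;
100–400 mAs), plus the 3×5 thickness–kernel cross grid for the purity
stage; ground truth at 0.35 mm (~135³×40 voxels). The whole pipeline runs
in well under a minute on one CPU. Ties, degenerate inputs and guard values
are listed with their modules above; one global seed fans out to stage
seeds via `SeedSequence([seed, stage])`.
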