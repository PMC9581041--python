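# Methods

This note documents the models, estimators, numerical choices, and known
limitations of `densestorm`. Everything quantitative stated here is
computed by the test suite or by `scripts/acceptance.py`.

## Data model

A localization table holds one row per fitted blink: coordinates (nm),
acquisition frame, and optionally photon count and precision. Tables are
treated as unordered sets; every operation is permutation-invariant.
Rendering bins localizations into a half-open `[lo, hi)` pixel grid
(default 5 nm pixels), origin at the extent's low corner, x rightward /
y downward. Files in camera-pixel units are converted on read with a camera
pixel size (default 108 nm). The HDF5 dialect is a single structured
dataset named `locs`, the convention of common SMLM fitting software; CSV
columns are matched through a configurable alias list.

Isolated localizations — fewer than `min_neighbors` (default 2) other
localizations within `radius` (default 50 nm) — are removed before building
training targets. The criterion and defaults are this package's choice (the
removal step itself is standard preprocessing but its parameters are rarely
reported); both are configurable and recorded in run manifests.

Sparse subsets are *contiguous frame windows*: a start frame is drawn
uniformly among those from which the target count is reachable, and the end
frame is chosen so the window's localization count is closest to
`fraction x total`. Contiguity preserves the temporal blinking structure
of a genuinely shorter acquisition, which is what the sparse-input use case
emulates.

## Kernel density estimation

`gaussian_kde` is plain convolution with a unit-mass isotropic Gaussian
(zero padding, truncation at 6 sigma); `sigma = 0` is the identity.

`anisotropic_kde` adapts the kernel per pixel. In an odd window (default
11 x 11 px) around pixel `i`, the intensity-weighted mean offset `mu_i` and
covariance

    Sigma_i = sum_j I_j (d_j - mu_i)(d_j - mu_i)^T / sum_j I_j  +  eps * Id

are computed from the pixel offsets `d_j`. The kernel evaluates
`exp(-0.5 d^T (s^2 Sigma_i)^-1 d)` on the window grid and is renormalized
to unit sum; each source pixel's intensity is then *scattered* through its
own kernel. Choices worth making explicit:

- **Intensity weighting.** The covariance is weighted by `I_j` so the
  division by the window's total intensity is dimensionally coherent; an
  unweighted sum of outer products would measure window geometry, not the
  local structure of the signal.
- **Discrete renormalization instead of the analytic prefactor.** The
  continuous 2-D Gaussian normalization is irrelevant after discretization
  on an 11 x 11 grid; renormalizing the sampled kernel to unit sum makes
  mass conservation exact by construction.
- **Scale convention.** The user-facing scale `s` multiplies the covariance
  as `s^2 Sigma`, so kernel *width* scales linearly in `s`; `s = 1..4` spans
  1x-4x the locally estimated width.
- **Scatter, not gather.** Scattering conserves total intensity exactly
  (each kernel sums to 1); the gather form does not. The two coincide only
  for spatially constant kernels.
- **Regularization.** `eps = 0.25 px^2` on the diagonal gives rank-deficient
  covariances (e.g. a perfect line of intensity) a sub-pixel width floor.
  All-zero windows carry no intensity and contribute nothing.
- **Boundaries.** Zero padding for both the covariance windows and the
  kernel scatter; conservation statements exclude a border band of
  `window // 2` pixels, where kernel mass leaves the image.

On isotropic content the adaptive estimator reduces to the Gaussian one
(verified at matched second moments); on filaments it smooths along the
axis while keeping the cross-filament edge sharper than an isotropic blur
of matched along-axis bandwidth (verified as an FWHM inequality).

## Fourier Ring Correlation

The centered spectra are partitioned into annuli by *rounded* integer
radius about the DC bin — the common binning in the FRC literature; the DC
term (total intensity) is excluded and samples beyond the Nyquist ring
`N/2` are discarded. Frequencies are reported as `f = r/N` cycles/pixel
(Nyquist 0.5). Only the real part of the cross term enters the numerator;
the denominator uses squared magnitudes. Rings with zero energy yield NaN
and are flagged rather than silently zeroed.

The cut-off is the first ring below the threshold (default 1/7), reported
with the Nyquist frequency and a "not crossed" flag when the curve stays
above it; an optional centered moving average (default off; the acceptance
analyses use a 5-ring window on split-half curves of count histograms,
whose per-ring noise otherwise triggers spurious early crossings) smooths
the curve before thresholding. The area statistic is the *mean* of ring
values up to `f_limit x Nyquist` — a mean rather than the plain sum so that
identical images give exactly 1 (loss 0) independent of image size.

## Differentiable losses

The area-FRC loss `1 - mean-ring-FRC` is implemented as a single primitive
with an analytic adjoint: the gradient of each ring's correlation with
respect to the spectrum is propagated through the inverse transform. A
constant `1e-8` under the normalization square root keeps gradients finite
for near-empty rings. The gradient is validated against central finite
differences (relative error < 1e-3 on 16 x 16 inputs; in practice ~1e-8).

MS-SSIM follows the standard 5-level formulation (11 x 11 Gaussian window,
sigma 1.5, conventional level weights, contrast-structure terms at the fine
levels and full SSIM at the coarsest, weights renormalized when fewer
levels are used). Negative contrast terms are clamped at zero before the
fractional powers. The single-level value matches scikit-image's SSIM to
numerical precision. Desk-scale 64-px patches support at most 3 levels.

Neither FRC (scale-invariant) nor MS-SSIM pins absolute intensity, so the
combined objective adds a small L1 term (default weight 0.1 against 1.0 for
the other two) to anchor background and total intensity.

## Generator and training

The generator is the pix2pix encoder/decoder: 4 x 4 stride-2 convolutions
with LeakyReLU(0.2) and filter schedule 64-128-256-512-…-512 over eight
levels, a mirrored transposed-convolution decoder with ReLU and skip
concatenations, and a tanh head. Batch normalization (absent only from the
first encoder level, as in pix2pix) is used in all profiles; running
statistics are applied at inference, which makes prediction deterministic
and independent of tiling. This is not cosmetic: without normalization the
freshly initialized network outputs near-zero amplitudes, the
scale-invariant FRC gradient (which grows as the inverse spectral
amplitude) then dwarfs the MS-SSIM and L1 gradients by about three orders
of magnitude, and training collapses onto the FRC term alone.

Reduced profiles are first-class: `desk` (5 levels, 64-256 filters, 64-px
patches) and `tiny` (3 levels, 16-64 filters) for CPU-scale runs; the full
profile reproduces the 8-level architecture at 512-px patches.

Training pairs: the target is the KDE density of the full (cleaned)
dataset; the input is the histogram of a frame window holding a uniform
5-30% of the localizations, rendered on the same grid. Registered random
crops are rotated by a continuous random angle (bilinear, reflection
padding) and center-cropped so rotation voids stay outside the training
patch; right-angle rotations are exact. Crops whose target patch is
(nearly) empty are redrawn — an all-zero target has no FRC normalization
and teaches nothing.

Normalization (unstated in the original training recipes, so fixed here):
targets are scaled by the 99.9th percentile of their positive values and
mapped to [-1, 1] with clipping; sparse count histograms are scaled by the
median positive count (usually 1), i.e. an occupancy-style mapping —
under a percentile scale a single-count pixel would land at mid-gray and
the input would be nearly invisible to the network. Losses are evaluated
after mapping both images back to density units, so logged values are in
physical units. The inverse mapping (with the training-time target scale)
restores predicted densities, clipped at zero.

Optimization is ADAM with lr 2e-4, beta1 0.5, batch 4; every loss term is
logged per epoch for training and validation, the best-validation weights
are restored at the end, and a non-finite loss aborts with the offending
batch identified. Two runs with the same seeds reproduce loss histories
exactly (pure numpy arithmetic; no framework nondeterminism).

Inference pads inputs to a multiple of `stride^depth` (reflection) and
tiles images larger than the training patch with 25% overlap and linear
ramp blending; with eval-mode normalization, tiled and single-pass outputs
agree except for residual border-padding effects (median difference 0,
90th percentile well below 1% of the output range).

## Simulator

Filaments are discretized worm-like chains (10 nm step, heading variance
`step / persistence`, default persistence 200 um — microtubules are nearly
straight on a 4 um field), entering from a random field edge and required
to reach at least half the field side in arc length. Labeling sites are a
uniform Poisson process along the arc (default 0.5 sites/nm — dense
immunostaining); each site sits on the projected microtubule surface
(offset `R sin(phi)`, `phi` uniform, R = 12.5 nm, the bare microtubule
radius); each site blinks Poisson(2.0) times, each blink lands in a
uniformly random frame and is perturbed by isotropic Gaussian noise of the
localization precision (default 10 nm). The filament-pair generator places
two parallel straight filaments at an exact center-to-center distance.

What the simulator deliberately omits: photokinetics (no on/off duty-cycle
correlations; blinks are uniform over frames), photon-count-dependent
precision, antibody linkage geometry (the label offset models the bare
tube radius only, so simulated filaments are *narrower* than real
immunolabeled microtubules, whose effective label radius is roughly twice
as large), background/false localizations, and drift. Passing tests
therefore demonstrate correctness of the pipeline on idealized filament
data, not performance on experimental images.

## Evaluation

PSNR (target dynamic range), MSE, MS-SSIM (levels adapted to image size),
and area-FRC are computed per prediction/target pair with mean and SEM.
The frequency-resolved FRC improvement is the pointwise difference between
the output-vs-target and input-vs-target curves.

Two-filament resolution: profiles are sampled perpendicular to the known
(simulated) filament axes, averaged over 500 nm of axial length at the
image pixel size. A profile counts as resolved when exactly two maxima with
prominence >= 10% of the profile maximum flank an interior minimum below
80% of the lower peak. The *resolution capability* is the separation at
which the resolved fraction over repeats crosses 50%, linearly interpolated
between tested distances; when even the smallest tested distance is mostly
resolved the capability is reported as that distance with a `below_grid`
flag, and its spread is a bootstrap standard deviation over repeats. Under
the simulator's default geometry (bare-tube label offset, 10 nm precision)
the reconstruction preserves the narrow simulated filament profiles, and
80 nm pairs are resolved in every repeat — the measured capability is a
bound (<= 80 nm) rather than an interior crossing; the acceptance script
additionally scans a wider distance grid for the actual crossing.

## Problem sizes

The packaged experiments run at reduced scale, chosen as a practical
CPU-size study: 4 x 4 um fields (800 x 800 px at 5 nm), 16 training pairs
of 64-px patches, 60-100 epochs with the desk/tiny profiles, and 20
simulation repeats per tested distance. The full-scale configuration
(512-px patches, 8-level generator, 1000 epochs) is expressible through the
same configs but is not exercised by the tests.

## Known limitations

- The tensor engine is float64 numpy on a single core; it is sized for the
  desk profiles, not for full-scale 512-px training.
- Batch-normalization statistics are taken from small batches; very small
  batch sizes make early training noisy.
- The two-peak criterion's prominence/valley thresholds are heuristic
  (configurable and logged); resolution capability depends on them near the
  crossing.
- FRC values depend on image content; comparisons are meaningful within an
  experiment, not across different structures.
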