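# densestorm

Deep-learning reconstruction of dense single-molecule localization
microscopy (SMLM) images from sparse localization subsets.

In SMLM (e.g. *d*STORM), resolution is limited not only by localization
precision but also by localization *density*: a structure sampled by too few
emitters cannot be reconstructed no matter how precisely each blink is
fitted. `densestorm` trains a U-Net-style image-to-image network to predict
the dense underlying fluorophore density of filamentous structures
(microtubules) from a histogram rendering of a small, temporally contiguous
subset of the localizations. It is aimed at SMLM practitioners and methods
developers who want shorter acquisitions or work with inherently sparse
labeling.

Two bespoke components sit at the core:

- **Anisotropic adaptive kernel density estimation** for ground-truth
  generation. A localization histogram `I` is smoothed per pixel `i` with a
  multivariate Gaussian kernel `K(x_i, x_j) ∝ exp(−½ (x_i−x_j)ᵀ Σ_i⁻¹ (x_i−x_j))`
  whose covariance `Σ_i = Σ_j I(x_j)(x_j−μ_i)(x_j−μ_i)ᵀ / Σ_j I(x_j)` is the
  intensity-weighted second moment of an 11 × 11 px window around `i`
  (scaled by a factor `s` as `s²Σ_i`). Along a filament the kernel elongates
  with the structure, smoothing along the axis while keeping edges sharp —
  unlike an isotropic Gaussian blur.

- **A differentiable area-FRC loss.** Fourier Ring Correlation compares two
  images ring-by-ring in frequency space,
  `FRC(r) = Re Σ_r F_x F_y* / √(Σ_r|F_x|² Σ_r|F_y|²)`, with `f = r/N` and the
  conventional 1/7-threshold crossing read as image resolution. The training
  loss is `L(f′) = 1 − mean of FRC(r) for f ≤ f′·Nyquist` (default
  `f′ = 0.2`), implemented with an analytic gradient and combined with
  MS-SSIM and a small L1 term:
  `L = w_frc·L_FRC + w_mssim·(1 − MS-SSIM) + w_l1·⟨|pred − target|⟩`.

The generator follows the pix2pix architecture: eight 4 × 4 stride-2
convolutions (filters 64-128-256-512-…-512, LeakyReLU), a mirrored
transposed-convolution decoder with skip connections (ReLU), and a tanh
head. Training uses ADAM (lr 2·10⁻⁴, β₁ = 0.5) on registered 750 → 512 px
crop pairs with continuous rotation augmentation; reduced "desk" and "tiny"
profiles support CPU-scale work. A worm-like-chain microtubule simulator
makes every stage testable without experimental data.

## Worked example

```python
import numpy as np
from densestorm import render_histogram, frc_curve, area_frc, cutoff_frequency
from densestorm.localization_io import split_half, split_by_frame_window
from densestorm.simulator import generate_filaments, simulate_localizations

rng = np.random.default_rng(1)
scene = generate_filaments(8, 4000, rng=rng)        # 8 filaments, 4 x 4 um
locs = simulate_localizations(scene, rng)           # ~33,000 localizations

# split-half FRC resolution of the full rendering (5 nm pixels)
a, b = split_half(locs, rng)
curve = frc_curve(render_histogram(a, 5.0, (0, 4000, 0, 4000)),
                  render_histogram(b, 5.0, (0, 4000, 0, 4000)))
print(cutoff_frequency(curve, pixel_size=5.0, smooth_window=5))
# {'frequency': 0.1225, 'crossed': True, 'resolution_nm': 40.816...}

# similarity of a 10% frame-window subset to the full rendering
sub, _ = split_by_frame_window(locs, 0.1, rng)
sub_img = render_histogram(sub, 5.0, (0, 4000, 0, 4000))
full_img = render_histogram(locs, 5.0, (0, 4000, 0, 4000))
print(round(area_frc(frc_curve(sub_img, full_img), 0.2), 3))
# 0.758
```

A split-half resolution of ≈ 41 nm is typical for this labeling density and
10 nm localization precision; the area-FRC of 0.76 quantifies how much
low-frequency structure a 10% subset already shares with the full image
(identical images give 1, unrelated noise ≈ 0). Training and prediction:

```bash
densestorm simulate --n-filaments 8 --field 4000 --seed 1 locs.hdf5
densestorm train --profile desk --kde-method anisotropic --seed 1 locs.hdf5 model.npz
densestorm predict --model model.npz --pixel-size 5 locs.hdf5 reconstruction.tif
densestorm resolve --model model.npz --distances 80,90,100 --repeats 20 resolution.json
```

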