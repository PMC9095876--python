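# Methods

This note records the forward model, the reconstruction and learning
pipeline, the parameter choices with their rationale, and the known limits of
the synthetic generator. No empirical claim here goes beyond what the test
suite and `scripts/acceptance.py` compute.

## Forward model (`palocal.phantom`)

**Vessel phantoms.** A bifurcating tree is grown recursively inside a
rectangular region: each segment spawns two children whose radius shrinks by
0.7 and length by 0.75 per level (a Murray-like taper), with direction
perturbed by Gaussian noise (σ = 0.6 before re-normalization). Segments are
clipped at the region boundary. A two-straight-vessel phantom
(`parallel_vessel_pair`) serves as the canonical resolution target.

**Flowing absorbers.** Absorbers (red blood cells / dye droplets) travel
along segments with a per-frame step drawn uniformly from
[0.5, 1.5] × `mean_step` µm and respawn on a length-weighted random segment
when they exit; each carries a fixed amplitude in [0.5, 1.0] and a fixed
cross-sectional offset within 0.9 × the lumen radius.

**Imaging.** Each frame is the sum of separable Gaussian point-spread
functions (FWHM = 2.3548 σ) centered on the absorbers, plus a constant
background and additive Gaussian noise, clipped to [0, 1]. Pixel *i* is
centered at (i + 0.5) × pixel_size with the origin at the grid corner.
Preset geometries:

| preset | grid | pixel size (µm) | PSF FWHM (µm) |
|---|---|---|---|
| `ImagingConfig.orpam()` | 64 × 64 × 256 | 3.75 × 5 × 3 | 5 × 5 × 114 |
| `ImagingConfig.pact()`  | 896 × 1024 | 25 × 25 | 125 × 125 |

The OR-PAM axial PSF reflects the acoustic resolution limit (≈114 µm ≫ 3 µm
sampling), which is why 4× axial downsampling (256 → 64 samples, bicubic,
antialiased) loses no structure. Default noise σ = 0.02 of the dynamic range.

## Localization (`palocal.localization`)

Per frame: optional difference-of-Gaussians band-pass (σ, 2σ) → local maxima
above a relative `amplitude_threshold` → greedy suppression of maxima closer
than `min_separation` px (brightest kept) → intensity-weighted centroid in an
odd window on the raw frame. The centroid window should cover ±2 σ of the PSF
(≈ 4 σ_px + 1); a truncating window biases centroids toward the grid (the
measured max error on isolated noise-free blobs is 0.04 px with window 11 vs
0.21 px with window 7 at the PACT PSF), while an oversized window admits
neighbors in dense scenes.

The **dense** image superimposes all N frames (OR-PAM, `unit="frames"`) or
all N droplets (PACT, `unit="events"`); a **sparse** image uses a uniform
random subset of k. Events deposit at `floor(position × superres_factor)`;
`mode="sum"` counts events (droplet density), `mode="max"` preserves peak
amplitude; images are normalized to unit peak by default. The acquisition
speedup is N/k, e.g. 60/5 = 240000/20000 = 12.

This detector is a stand-in: it reproduces the sub-pixel localize-and-
superimpose principle but not any specific published detector chain
(no flow tracking, no drift correction, no adaptive thresholds).

## Metrics (`palocal.metrics`)

PSNR = 10 log₁₀(R²/MSE) (identical inputs → +inf sentinel). SSIM uses the
standard local-statistics form with an 11-pixel, σ = 1.5 Gaussian window,
C₁ = (0.01 R)², C₂ = (0.03 R)², population covariances, evaluated on the
valid interior (verified to match `skimage` bit-for-bit under these
settings). MS-SSIM multiplies contrast/structure terms from every dyadic
scale and the luminance term at the coarsest scale, each raised to the
normalized weights (0.0448, 0.2856, 0.3001, 0.2363, 0.1333), with 2× average
pooling between scales; negative contrast-structure means are clamped at 0.
When `scales=None` the count auto-clamps to the largest feasible number
(≤ 5) for the input size — a 64×64 image supports 3; requesting more raises
an error naming the maximum. All metrics are dimension-agnostic; size-1 axes
are squeezed, so a flat 3D volume scores exactly as its 2D slice.

## Networks and training (`palocal.networks`, `palocal.training`, `palocal.grad`)

The generators are U-Nets of exactly 17 convolutional layers (4 levels × 2
convs down, 4 × (upsample conv + 1 conv) up, 1 output conv), with long skip
concatenation and a parameter-free short skip (adding a 3-wide stride-1
max-pooled residual, which emphasizes local maxima — the localization
targets). The 3D variant (two input channels: sparse + regular volume) uses
transposed-convolution upsampling, batch normalization and spatial dropout;
the 2D variant (sparse image only) uses pixel-shuffle upsampling and omits
both. Channel widths: 3D base 64 capped at 512 (44.6 M parameters), 2D base
128 capped at 1024 (106.3 M) — chosen to land near the ~43 M / ~102 M totals
the architecture is known for. Discriminators are 5-layer patch classifiers
(4 stride-2 leaky-ReLU convolutions + sigmoid output; 4.7 M / 1.6 M
parameters); their mean patch probability feeds the adversarial losses.

Losses (MAE = mean absolute error over pixels, M = MS-SSIM):

* 3D: `0.01·MAE − log D(G(x))`
* 2D pre-training: `0.3·MAE + 0.7·(1 − M)`
* 2D fine-tuning: `0.03·MAE + 0.07·(1 − M) − log D(G(x))`
* discriminator: `−[log D(y) + log(1 − D(G(x)))]`

Probabilities are clamped to [1e−7, 1 − 1e−7] before logarithms. Training
uses He-normal initialization, Adam (β = (0.5, 0.999)), weight decay 1e−5,
random crops plus lateral (never axial) flips at p = 0.5, and keeps the
checkpoint with the highest validation MS-SSIM. Everything runs on a small
reverse-mode autodiff engine (`palocal.grad`) whose operations are validated
against central-difference gradients in the test suite; optimization runs in
float32 (the differentiable MS-SSIM clamps contrast-structure terms to
[1e−6, 1] so fractional powers stay finite), while evaluation metrics run in
float64.

## Desk-scale studies (`palocal.experiments`)

Full-scale training (10⁸ parameters, 896×1024 images) is far too slow for a
bundled CPU test suite, so the learning claims are demonstrated at desk scale
with the same pipeline:

* **Sparse-to-dense experiment** — 72 synthetic 64×64 pairs (64 train / 8
  validation), generated by the full simulate→localize→superimpose pipeline
  with a 12× event reduction; a base-8, 2-level pixel-shuffle generator
  (≈24 k parameters); 40 pre-training epochs then 10 adversarial fine-tuning
  epochs with a fresh discriminator (batch 2, lr 2e−4); best checkpoint
  across both stages. Reported: generator-vs-dense and sparse-vs-dense
  validation MS-SSIM.
* **Sparsity sweep** — one simulated 60-frame series; sparse images at
  k ∈ {2, 5, 10, 30, 60} frames, 20 random subsets per k averaged to reduce
  draw noise; Spearman ρ between k and mean MS-SSIM against the dense image.
* **Resolution study** — two parallel vessels 75 µm apart (under the 125 µm
  PSF): 480 frames at 2 absorbers/frame with fast flow, so simultaneous
  absorbers from the two vessels rarely share a centroid window (overlap
  biases centroids inward) and per-vessel visit counts stay balanced. Peak
  counts on cross-vessel mean profiles (localization profile smoothed by one
  superresolution bin; 20 % prominence floor): one regular ridge, two
  localized ridges.

## Limitations

* The phantom is geometric, not hemodynamic: straight-segment trees, uniform
  flow speed distribution, no pulsatility, no vessel curvature, no
  scattering, no depth-dependent fluence or attenuation, stationary Gaussian
  noise, and a spatially invariant Gaussian PSF (real PACT PSFs vary with
  position and are not separable).
* The localization operator is a generic DoG/centroid detector; published
  systems add flow tracking and drift/motion correction.
* Desk-scale training results demonstrate the sparse-to-dense ordering, not
  any published in vivo image-quality values; those require the original
  datasets and full-size networks.
* The autodiff engine is single-threaded NumPy: adequate for the bundled
  experiments, orders of magnitude slower than GPU frameworks at full scale.
* `make_sparse` draws subsets without replacement per image; correlated
  frame-to-frame absorber motion means sparse images are not i.i.d.
  subsamples of independent events, just as in real acquisitions.
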