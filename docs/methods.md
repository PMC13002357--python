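# Methods

## The problem

Supervised retinal vessel segmentation is trained on hand-traced masks, and
hand tracing thin vessels is imprecise: annotators place boundaries and
centerlines a few pixels off, especially for capillaries near the
resolution limit. This package provides a controlled way to study that
failure mode — it injects *positional* label noise of known strength into
training annotations and measures how segmentation quality responds.

## Pipeline

### Preprocessing

Color fundus images are reduced to one channel, standardized, and
contrast-enhanced in a fixed order: grayscale → z-score → 8-bit rescale →
CLAHE → gamma. Parameters, units and defaults:

| parameter | meaning | default |
|---|---|---|
| `grayscale_mode` | ITU-R 601 luma (0.299, 0.587, 0.114) or the green channel | `luma` |
| `gamma` (γ) | tone-curve exponent; γ > 1 brightens dark areas | 1.6 |
| `clahe_clip` (c) | histogram clip limit, multiples of the mean bin height | 2.0 |
| `clahe_tiles` (t) | tile grid size per dimension | 8 |

The z-score output is real-valued while CLAHE operates on 8-bit
histograms, so an affine min–max rescale onto [0, 255] bridges the two
stages. CLAHE clips each of the 256 per-tile bins at `c · tile_area / 256`,
redistributes the excess uniformly over all bins in a single pass, maps
intensities through the per-tile CDF, and blends adjacent tile mappings
bilinearly between tile centers (clamped at borders). Everywhere
intensities are quantized, rounding is half-away-from-zero — chosen once
for cross-platform bit-stability. Constant (zero-variance) images raise an
error rather than silently returning zeros. Statistics are computed over
the full frame by default; `fov_only` restricts the z-score statistics to
FOV pixels (the CLAHE histograms remain full-frame).

### Balanced patch sampling

Training samples `n` patches of size `s×s` (defaults 2200 and 48) per
image, every patch fully inside the FOV, positions drawn with replacement
(2200 overlapping windows cannot be disjoint on a fundus image). A window
counts as *small-vessel* when its label holds between 1 and 200 white
pixels; the lower bound is 1 because an empty window contains no vessel to
oversample (`include_empty` restores the literal 0–200 range). The uniform
share `P` solves `f·P + (1−P) = g` for the probe-estimated small-vessel
fraction `f` and target `g = 0.5`; `floor(P·n)` patches are uniform and the
remainder comes from the small-vessel pool. `f` is re-estimated per dataset
by probing 1000 random windows rather than hard-coding the ≈ 0.37 value
observed on real fundus data. Rotation augmentation appends exact 90°
array rotations (no interpolation), quadrupling the pool.

At test time the image is zero-padded bottom/right to the stride grid
(stride 10 by default), every tile is predicted, and overlapping
predictions are averaged; stride = patch size reproduces the seamless
(non-overlapping) ablation arm.

### The segmentation network

A lightweight U-Net operating on `s×s` single-channel patches:

- encoder stage: two same-padded 3×3 convolutions, each with batch
  normalization and ReLU, then 20 % dropout and a stride-2 max pool;
  channels double per stage;
- decoder stage: 2×2 nearest-neighbor upsampling, a channel-halving 3×3
  convolution, skip concatenation, then a conv pair mirroring the encoder;
- head: a 1×1 convolution to 2 channels with per-pixel softmax.

Defaults are depth 4 and base width 16 (≈ 2.6 M parameters); the scaled
experiments use depth 2 / width 4. The *dynamic attention* block refines
the bottleneck and (optionally) each skip map: the spatial positions of the
encoder map form the key/value sequence `H`, the aligned decoder map is
mean-pooled into the query state `d`, and scaled dot-product attention
(`S = QKᵀ/√d_k`, row-softmax `A`, context `C = A·V`, output
`W_o·[C; d]`) produces a channel vector broadcast-added to the refined
features. The attention weights are per-level, the normalization of the
scores is a row-wise softmax, and the pooled-vector reading of the decoder
state is a documented design choice — the minimal one consistent with the
block's matrix shapes.

Training is SGD with momentum (defaults: 20 epochs, batch 32, learning
rate 0.1, momentum 0.9) minimizing mean pixel-wise cross entropy against
one-hot labels, with logs clamped at 1e-12. The whole network — forward,
backward, and the optimizer — is implemented in NumPy with channels-last
shifted-GEMM convolutions; gradients are verified against central finite
differences in float64 during development, and the test suite re-checks
the structural identities (softmax normalization, attention arithmetic,
parameter counts) analytically.

### Positional label noise

For a patch with center `c = ((s−1)/2, (s−1)/2)` (0-based pixel centers)
and radius `R = s/2`, each pixel `p` with `r = ‖p−c‖₂ ≤ R` is resampled
from `p' = c + (r'/(r+ε))(p−c)` where `r' = R·(r/R)^β` and ε = 1e-8;
pixels beyond `R` are untouched. β > 1 zooms the central region in, β < 1
zooms out, β = 1 is the identity. The noise level λ is mapped to
β = 1 + λ (zoom-in, default), β = 1/(1+λ) (zoom-out), or a per-patch
random choice — only the displacement magnitude, not its direction, is
treated as the noise strength. Labels are resampled nearest-neighbor so
binarity is preserved without a second thresholding rule (bilinear + 0.5
threshold available). Source points outside the window read background;
deformation fields are built per patch. Mixing at ratio ρ deforms exactly
`round(ρ·N)` patches chosen uniformly without replacement and flags them,
so the cleaning arm can later drop exactly the corrupted subset.

The baseline image-level corruptions use strengths not tied to any
published calibration: Gaussian σ = λ·25 gray levels, down/upsampling by
1 + 3λ, box-blur width 1 + 2·round(4λ), and the fovea blur confined to the
central disc with a linear radial ramp. They are visually plausible
severities, exposed in the API, and should be treated as approximate.

### Metrics

Accuracy, specificity, sensitivity, precision and F1 from the confusion
counts, and the ROC AUC of the probability map, all restricted to FOV
pixels — the standard convention for fundus benchmarks, and consistent
with the FOV discipline used when sampling patches. Thresholding is
strictly "greater than 0.5"; exact ties resolve to background for
determinism. Degenerate denominators (no predicted positives, single-class
truth for AUC) yield 0 / NaN with an explanatory flag instead of raising.
AUC is computed per image; pooled variants can be built from the saved
probability maps.

## Synthetic data

The generator emulates the features of fundus photographs that the
pipeline actually exercises: a circular FOV (dark surround), a radially
falling illumination field with Gaussian texture (σ = 5 gray levels), and
2 branching vessel trees per image — recursive midpoint-displaced
segments whose width decays by 0.55 per generation from 8 px trunks to a
1 px floor, rasterized by distance-to-centerline thresholding so widths
are exact and the binary mask is the exact support. Vessels are darker
than the background (contrast 60), as in real green-channel fundus images;
an optional central light reflex adds a bright 1 px ridge along trunks.
With these defaults the vessel fraction inside the FOV is ~6–12 %, the
same order as real retinal vasculature, and a 48 px window census contains
both small-vessel (≤ 200 white px) and trunk (> 200) patches.

What the generator does *not* reproduce: pathology (hemorrhages,
exudates), JPEG artifacts, inter-observer annotation disagreement, color
information, and the full 565×584 resolution. Passing tests therefore
demonstrate that the pipeline's mechanics and the *direction* of the
noise-sensitivity effects are correct, not that absolute scores on real
fundus benchmarks are reproduced.

## Scaled-down reference experiment

The stochastic acceptance checks and `scripts/acceptance.py` run the
sweeps at desk scale: 4 training / 2 test images of 128×128, 200 patches
per image, 32×32 patches (deformation radius R = 16), a depth-2 width-4
model, 10 epochs, no rotation augmentation, three seeds (single seed in
the script). These sizes are the package's reference configuration for
fast, deterministic verification; the CLI runs the full-size protocol
(2200 patches, 48 px, 20 epochs, rotations) on manifest-described data.
Under the reference configuration the qualitative findings hold: full
heavy deformation (λ = 0.8, ρ = 1) lowers mean test sensitivity and F1
below the clean baseline on every seed; mean F1 is non-increasing in the
noise ratio at λ = 0.6; and at ρ = 0.75 training on the 25 % clean subset
beats training on the full mixed pool.

## Numerical and design notes

- **Seeding.** Every stochastic stage derives its seed as
  `blake2s(run_seed, stage_name, qualifiers) mod 2³¹`, so sweeps are
  reproducible and conditions are independently seeded; one fresh model is
  trained per sweep condition to avoid warm-start leakage.
- **Rounding.** Half-away-from-zero wherever intensities or probabilities
  are quantized; ties at the classification threshold go to background.
- **Degenerate inputs.** Constant images raise; an empty small-vessel pool
  raises unless `fallback_uniform` reallocates the share; a missing FOV
  mask substitutes the full frame with a warning; vessel pixels outside
  the FOV are removed by intersection and logged.
- **Warp fragmentation.** Nearest-neighbor resampling of ~1 px capillaries
  under the radial warp fragments them (component counts grow tens of
  percent at λ = 0.4); this is the degradation phenomenon under study, and
  the regression tests freeze its measured extent rather than assume
  topology is preserved.
- **Known limitations.** No vessel-enhancement filtering or illumination
  correction beyond CLAHE/gamma; no boundary-erosion or vessel-erasure
  noise models; the attention block's decoder state is a pooled vector
  (not a spatial map); absolute benchmark scores on DRIVE-class data are
  out of scope for the test suite, though the CLI can run them when a
  manifest is supplied.
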