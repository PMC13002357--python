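# vesselnoise

Noise-robust, patch-based retinal vessel segmentation with positional
label-noise simulation.

Manual vessel annotations in fundus photography are error-prone: thin,
tortuous capillaries are easily traced a few pixels off their true course.
`vesselnoise` implements a complete pipeline for studying how such
*positional* annotation errors affect a segmentation model:

- **Preprocessing** — grayscale conversion, z-score normalization
  `I' = (I − μ)/σ`, contrast-limited adaptive histogram equalization
  (CLAHE, clip limit `c`, tile grid `t×t`), and gamma adjustment
  `J = 255·(I/255)^(1/γ)` with γ > 1 brightening the dark vessel regions.
- **Balanced patch sampling** — overlapping 48×48 patches drawn entirely
  inside the field of view (FOV). A fraction `P` is sampled uniformly and
  the rest only from windows with 1–200 vessel pixels ("small-vessel"
  patches), solving `f·P + (1−P) = g` to lift the small-vessel share from
  the observed `f` (≈ 0.37) to a target `g` (0.5), giving `P ≈ 0.8`.
  Patches are quadrupled by 90°/180°/270° rotation.
- **Segmentation model** — a lightweight U-Net (3×3 conv pairs with batch
  normalization, ReLU and 20 % dropout; 2× max-pool encoder; nearest-
  neighbor-upsampling decoder with skip connections) whose bottleneck and
  skip features are refined by a *dynamic attention* block: scaled
  dot-product attention `S = QKᵀ/√d_k`, `A = softmax(S)`, `C = A·V`,
  `out = W_o·[C; d]` of the pooled decoder state over the spatial positions
  of the encoder map. Trained with pixel-wise cross entropy on one-hot
  {background, vessel} labels, SGD (lr 0.1, momentum 0.9). The network is
  implemented directly in NumPy (forward and backward passes), so the
  package has no deep-learning-framework dependency.
- **Positional label noise** — a non-linear radial deformation of the label
  patch: with center `c` and radius `R = s/2`, each pixel at distance
  `r ≤ R` is resampled from radius `r' = R·(r/R)^β`. The noise level λ maps
  to β = 1 + λ (zoom-in), β = 1/(1+λ) (zoom-out), or a random direction;
  the noise ratio ρ controls which fraction of training patches is
  deformed. Baseline image-level corruptions (Gaussian noise, low
  resolution, uniform blur, fovea blur) are included for comparison.
- **Inference and metrics** — stride-10 overlapping tiling with averaged
  recombination, thresholding at 0.5, and Acc/Sp/Sn/Precision/F1/AUC
  computed inside the FOV.
- **Experiment harnesses** — noise-level, noise-ratio and noise-type
  sweeps, plus a cleaning comparison (train on the full noisy pool vs only
  the clean subset), each retraining a fresh seeded model per condition.
- **Synthetic data** — a seeded generator of fundus-like images (circular
  FOV, radial illumination falloff, branching vessel trees with widths
  from ~8 px trunks to 1 px capillaries, exact ground-truth masks), so
  every stage runs at desk scale with no dataset download. Real DRIVE-style
  datasets are supported through a CSV manifest.

## Worked example

```python
import numpy as np
from vesselnoise.config import ExperimentConfig, TrainConfig
from vesselnoise.experiments import preprocess_dataset, run_condition
from vesselnoise.model import ModelConfig
from vesselnoise.noise import NoiseSpec
from vesselnoise.patches import SamplingConfig
from vesselnoise.synth import SynthConfig, generate_dataset

cfg = ExperimentConfig(
    sampling=SamplingConfig(patches_per_image=200, patch_size=32),
    model=ModelConfig(patch_size=32, depth=2, base_channels=4),
    train=TrainConfig(epochs=10),
    rotate=False,
)
train_s, test_s = generate_dataset(SynthConfig(seed=11), n_train=4, n_test=2)
train_p, test_p = preprocess_dataset(train_s, cfg), preprocess_dataset(test_s, cfg)

for lam in (0.0, 0.8):
    spec = NoiseSpec(noise_level=lam, noise_ratio=1.0 if lam else 0.0,
                     corruption="nonlinear")
    _, reports, _ = run_condition(train_p, test_p, cfg, spec, seed=101)
    print(f"lambda={lam}: Sn={np.mean([r.sn for r in reports]):.3f} "
          f"F1={np.mean([r.f1 for r in reports]):.3f}")
```

Output:

```
lambda=0.0: Sn=0.989 F1=0.904
lambda=0.8: Sn=0.729 F1=0.619
```

Training on clean synthetic labels recovers the vessels almost perfectly
(sensitivity 0.99); deforming every training label at level λ = 0.8 drops
sensitivity to 0.73 and F1 to 0.62 on *clean* test annotations — the model
inherits the positional bias of its supervision.

The same experiments run from the shell on any manifest-described dataset:

```bash
vesselnoise synth --n-train 4 --n-test 2 --seed 11 --out-dir data/
vesselnoise sweep --mode level --manifest data/manifest.csv --out-dir results/
vesselnoise clean-compare --manifest data/manifest.csv --level 0.6 --out-dir results/
```

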