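"""Balanced patch extraction, rotation augmentation, and tiled inference.

Training uses fixed-size patches sampled with replacement from positions
whose full window lies inside the field of view. To counter the class
imbalance between capillaries and trunk vessels, a fraction ``P`` of the
patches is drawn uniformly and the remainder only from positions whose
label window qualifies as a small-vessel patch (between 1 and
``small_vessel_bound`` vessel pixels). ``P`` solves the balance equation
``f*P + (1-P) = g`` for a source small-vessel fraction ``f`` and target
``g`` (f=0.37, g=0.5 gives P ~ 0.8).

At test time the image is zero-padded on the bottom/right, cut into a dense
overlapping stride grid, and the per-patch probability maps are averaged
back into a full-frame map.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from vesselnoise.dataio import FundusSample

ROTATION_ANGLES = (90, 180, 270)


class SamplingError(ValueError):
    pass


@dataclass
class SamplingConfig:
    patches_per_image: int = 2200
    patch_size: int = 48
    random_fraction: float = 0.8
    small_vessel_bound: int = 200
    test_stride: int = 10
    include_empty: bool = False  # count 0-white-pixel patches as "small vessel"
    fallback_uniform: bool = False  # empty small-vessel pool -> uniform sampling

    def validate(self) -> "SamplingConfig":
        if self.patch_size < 1 or self.test_stride < 1 or self.patches_per_image < 1:
            raise ValueError("patch size, stride and patch count must be positive")
        if not 0.0 <= self.random_fraction <= 1.0:
            raise ValueError("random_fraction must lie in [0, 1]")
        if self.small_vessel_bound < 0:
            raise ValueError("small_vessel_bound must be >= 0")
        return self


@dataclass
class PatchSet:
    """Fixed-size image/label windows with their source coordinates.

    ``images`` is (N, s, s) in the source image dtype, ``labels`` (N, s, s)
    binary uint8, ``origins`` (N, 2) 0-based top-left corners, and
    ``noisy`` an optional (N,) bool flag array marking corrupted labels.
    """

    images: np.ndarray
    labels: np.ndarray
    origins: np.ndarray
    sample_ids: np.ndarray
    noisy: Optional[np.ndarray] = None

    def __post_init__(self):
        n = self.images.shape[0]
        if self.labels.shape != self.images.shape:
            raise ValueError("images and labels must have identical shapes")
        if self.origins.shape != (n, 2) or len(self.sample_ids) != n:
            raise ValueError("origins/sample_ids do not match the patch count")
        if self.noisy is not None and self.noisy.shape != (n,):
            raise ValueError("noisy flags do not match the patch count")

    def __len__(self) -> int:
        return self.images.shape[0]

    @property
    def patch_size(self) -> int:
        return self.images.shape[1]

    def subset(self, idx) -> "PatchSet":
        return PatchSet(
            images=self.images[idx],
            labels=self.labels[idx],
            origins=self.origins[idx],
            sample_ids=self.sample_ids[idx],
            noisy=None if self.noisy is None else self.noisy[idx],
        )

    def with_labels(self, labels: np.ndarray, noisy: Optional[np.ndarray] = None) -> "PatchSet":
        return replace(self, labels=labels, noisy=noisy)


def concat_patchsets(sets: Sequence[PatchSet]) -> PatchSet:
    flags = [p.noisy for p in sets]
    noisy = None
    if all(f is not None for f in flags):
        noisy = np.concatenate(flags)
    return PatchSet(
        images=np.concatenate([p.images for p in sets]),
        labels=np.concatenate([p.labels for p in sets]),
        origins=np.concatenate([p.origins for p in sets]),
        sample_ids=np.concatenate([p.sample_ids for p in sets]),
        noisy=noisy,
    )


@dataclass
class TileLayout:
    """Stride grid used to tile an image and recombine patch predictions."""

    padded_shape: tuple[int, int]
    original_shape: tuple[int, int]
    origins: np.ndarray  # (n, 2)
    stride: int
    patch_size: int


def _check_binary(window: np.ndarray) -> np.ndarray:
    window = np.asarray(window)
    if not np.isin(np.unique(window), [0, 1]).all():
        raise ValueError("label window is not binary")
    return window


def count_white(label_window: np.ndarray) -> int:
    """Number of vessel (value 1) pixels in a binary label window."""
    return int(_check_binary(label_window).sum())


def is_small_vessel_patch(label_window: np.ndarray, bound: int = 200, include_empty: bool = False) -> bool:
    """True iff the window holds between 1 (or 0) and ``bound`` vessel pixels.

    An empty window contains no vessel to oversample, so the lower bound
    defaults to 1; ``include_empty`` admits empty windows too.
    """
    c = count_white(label_window)
    lo = 0 if include_empty else 1
    return lo <= c <= bound


def _window_sums(mask: np.ndarray, s: int) -> np.ndarray:
    """Sum of each s-by-s window of ``mask`` via an integral image; shape
    (H-s+1, W-s+1)."""
    ii = np.zeros((mask.shape[0] + 1, mask.shape[1] + 1), dtype=np.int64)
    np.cumsum(np.cumsum(mask, axis=0), axis=1, out=ii[1:, 1:])
    return ii[s:, s:] - ii[:-s, s:] - ii[s:, :-s] + ii[:-s, :-s]


def fov_interior_origins(fov_mask: np.ndarray, s: int) -> np.ndarray:
    """All (row, col) origins whose s-by-s window lies entirely inside the FOV."""
    if fov_mask.shape[0] < s or fov_mask.shape[1] < s:
        return np.empty((0, 2), dtype=np.int64)
    sums = _window_sums(fov_mask.astype(np.int64), s)
    return np.argwhere(sums == s * s)


def _gather_windows(raster: np.ndarray, origins: np.ndarray, s: int) -> np.ndarray:
    view = sliding_window_view(raster, (s, s))
    return view[origins[:, 0], origins[:, 1]].copy()


def estimate_small_vessel_fraction(
    sample: FundusSample,
    n_probe: int = 1000,
    seed: int = 0,
    cfg: SamplingConfig | None = None,
) -> float:
    """Fraction of uniformly probed FOV-interior patches that are small-vessel.

    Mirrors the probe used to calibrate the balance fraction: draw
    ``n_probe`` random positions, count white pixels in each label window,
    and report the qualifying fraction.
    """
    cfg = (cfg or SamplingConfig()).validate()
    s = cfg.patch_size
    valid = fov_interior_origins(sample.fov_mask, s)
    if len(valid) == 0:
        raise SamplingError(f"sample {sample.sample_id!r}: no FOV-interior patch position")
    rng = np.random.default_rng(seed)
    picks = valid[rng.integers(0, len(valid), size=n_probe)]
    counts = _window_sums(sample.vessel_mask.astype(np.int64), s)[picks[:, 0], picks[:, 1]]
    lo = 0 if cfg.include_empty else 1
    return float(np.mean((counts >= lo) & (counts <= cfg.small_vessel_bound)))


def solve_balance_fraction(source_fraction: float, target: float) -> float:
    """Solve ``f*P + (1-P) = g`` for the uniform share P, clamped to [0, 1]."""
    f, g = source_fraction, target
    if not 0.0 <= f < 1.0:
        raise ValueError("source fraction must lie in [0, 1)")
    if not f <= g <= 1.0:
        raise ValueError("target must lie in [source_fraction, 1]")
    return float(min(max((1.0 - g) / (1.0 - f), 0.0), 1.0))


def extract_training_patches(
    sample: FundusSample, cfg: SamplingConfig | None = None, seed: int = 0
) -> PatchSet:
    """Draw the balanced training patch set from one sample.

    ``floor(P*n)`` patches are sampled uniformly (with replacement) over
    FOV-interior positions; the remaining ``n - floor(P*n)`` only from
    positions whose label window qualifies as small-vessel. Deterministic
    given ``seed``.
    """
    cfg = (cfg or SamplingConfig()).validate()
    s, n = cfg.patch_size, cfg.patches_per_image
    image = sample.image
    if image.ndim != 2:
        raise SamplingError("extract_training_patches expects a single-channel image")
    valid = fov_interior_origins(sample.fov_mask, s)
    if len(valid) == 0:
        raise SamplingError(f"sample {sample.sample_id!r}: no FOV-interior patch position")
    rng = np.random.default_rng(seed)
    n_rand = int(math.floor(cfg.random_fraction * n))
    n_small = n - n_rand
    chosen = [valid[rng.integers(0, len(valid), size=n_rand)]]
    if n_small > 0:
        counts = _window_sums(sample.vessel_mask.astype(np.int64), s)[valid[:, 0], valid[:, 1]]
        lo = 0 if cfg.include_empty else 1
        pool = valid[(counts >= lo) & (counts <= cfg.small_vessel_bound)]
        if len(pool) == 0:
            if not cfg.fallback_uniform:
                raise SamplingError(
                    f"sample {sample.sample_id!r}: empty small-vessel pool "
                    "(set fallback_uniform to reallocate the share)"
                )
            pool = valid
        chosen.append(pool[rng.integers(0, len(pool), size=n_small)])
    origins = np.concatenate(chosen)
    return PatchSet(
        images=_gather_windows(image, origins, s),
        labels=_gather_windows(sample.vessel_mask, origins, s),
        origins=origins,
        sample_ids=np.full(n, sample.sample_id, dtype=object),
    )


def rotate_augment(patchset: PatchSet) -> PatchSet:
    """Append the 90/180/270-degree rotations of every patch (4x the size).

    Image and label windows rotate identically and exactly (array rotation,
    no interpolation); origins refer to the unrotated source window.
    """
    if patchset.images.shape[1] != patchset.images.shape[2]:
        raise ValueError("rotation augmentation requires square patches")
    imgs = [patchset.images] + [np.rot90(patchset.images, k, axes=(1, 2)) for k in (1, 2, 3)]
    labs = [patchset.labels] + [np.rot90(patchset.labels, k, axes=(1, 2)) for k in (1, 2, 3)]
    rep = lambda a: np.concatenate([a] * 4)
    return PatchSet(
        images=np.ascontiguousarray(np.concatenate(imgs)),
        labels=np.ascontiguousarray(np.concatenate(labs)),
        origins=rep(patchset.origins),
        sample_ids=rep(patchset.sample_ids),
        noisy=None if patchset.noisy is None else rep(patchset.noisy),
    )


def _grid_starts(extent: int, s: int, stride: int) -> np.ndarray:
    n = 1 if extent <= s else int(math.ceil((extent - s) / stride)) + 1
    return np.arange(n) * stride


def tile_test_patches(image: np.ndarray, cfg: SamplingConfig | None = None):
    """Cut an image into the overlapping stride grid used at inference.

    The image is zero-padded on the bottom/right so the grid covers it
    exactly; returns ``(TileLayout, patches)`` with one (s, s) window per
    grid origin.
    """
    cfg = (cfg or SamplingConfig()).validate()
    s, stride = cfg.patch_size, cfg.test_stride
    if stride > s:
        raise ValueError("test stride must not exceed the patch size (coverage gap)")
    h, w = image.shape
    rows = _grid_starts(h, s, stride)
    cols = _grid_starts(w, s, stride)
    hp, wp = rows[-1] + s, cols[-1] + s
    padded = np.zeros((hp, wp), dtype=image.dtype)
    padded[:h, :w] = image
    origins = np.stack(np.meshgrid(rows, cols, indexing="ij"), axis=-1).reshape(-1, 2)
    patches = _gather_windows(padded, origins, s)
    layout = TileLayout(
        padded_shape=(int(hp), int(wp)),
        original_shape=(h, w),
        origins=origins,
        stride=stride,
        patch_size=s,
    )
    return layout, patches


def recombine(patch_probs: np.ndarray, layout: TileLayout) -> np.ndarray:
    """Average overlapping per-patch probability maps into a full frame.

    Each output pixel is the arithmetic mean of every patch prediction that
    covers it; the zero-padding margin is cropped away.
    """
    patch_probs = np.asarray(patch_probs, dtype=np.float64)
    if patch_probs.shape[0] != len(layout.origins):
        raise ValueError(
            f"{patch_probs.shape[0]} rasters for {len(layout.origins)} tile origins"
        )
    s = layout.patch_size
    acc = np.zeros(layout.padded_shape, dtype=np.float64)
    cnt = np.zeros(layout.padded_shape, dtype=np.float64)
    for (r, c), prob in zip(layout.origins, patch_probs):
        acc[r : r + s, c : c + s] += prob
        cnt[r : r + s, c : c + s] += 1.0
    out = acc / cnt
    h, w = layout.original_shape
    return out[:h, :w]
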