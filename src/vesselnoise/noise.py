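"""Positional label noise via non-linear radial deformation, plus baseline
image corruptions and clean/noisy label mixing.

The deformation emulates the positional errors of manual vessel annotation.
For a patch with center ``c`` and radius ``R`` (half the shortest side),
each pixel ``p`` at distance ``r = ||p - c||`` inside the circle is resampled
from the source point

    r' = R * (r / R)^beta,     p' = c + (r' / (r + eps)) * (p - c),

while pixels with ``r > R`` are left untouched. ``beta > 1`` zooms the
central region in, ``beta < 1`` zooms it out; ``beta = 1`` is the identity.
The noise level ``lambda`` is the deformation distance and maps to
``beta = 1 + lambda`` (zoom-in), ``beta = 1 / (1 + lambda)`` (zoom-out),
or a per-patch random choice of the two — only the displacement magnitude,
not its direction, is treated as the noise strength.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from vesselnoise._seed import derive_seed
from vesselnoise.patches import PatchSet

EPSILON = 1e-8
CORRUPTION_KINDS = ("nonlinear", "gaussian", "lowres", "uniform_blur", "fovea_blur", "none")
DIRECTION_MODES = ("zoom_in", "zoom_out", "random")

#: Additive Gaussian corruption strength at lambda = 1, in 8-bit gray levels.
SIGMA_MAX = 25.0


@dataclass
class NoiseSpec:
    """One corruption condition: level, ratio, kind, direction and seed."""

    noise_level: float = 0.0
    noise_ratio: float = 0.0
    corruption: str = "nonlinear"
    direction_mode: str = "zoom_in"
    seed: int = 0

    def validate(self) -> "NoiseSpec":
        if not 0.0 <= self.noise_level <= 1.0:
            raise ValueError("noise level must lie in [0, 1]")
        if not 0.0 <= self.noise_ratio <= 1.0:
            raise ValueError("noise ratio must lie in [0, 1]")
        if self.corruption not in CORRUPTION_KINDS:
            raise ValueError(f"unknown corruption kind {self.corruption!r}")
        if self.direction_mode not in DIRECTION_MODES:
            raise ValueError(f"unknown direction mode {self.direction_mode!r}")
        return self


@dataclass
class DeformationField:
    """Per-pixel source offsets (dx, dy) realizing one radial deformation."""

    delta_x: np.ndarray
    delta_y: np.ndarray
    beta: float
    radius: float
    epsilon: float = EPSILON


def beta_from_level(lam: float, direction: str = "zoom_in", seed: int = 0) -> float:
    """Map a noise level to the radial exponent beta.

    zoom_in -> 1 + lam; zoom_out -> 1 / (1 + lam); random -> one of the two
    with equal probability (deterministic given ``seed``). lam = 0 gives
    beta = 1 (identity) in every mode.
    """
    if lam < 0:
        raise ValueError("noise level must be >= 0")
    if direction not in DIRECTION_MODES:
        raise ValueError(f"unknown direction mode {direction!r}")
    if direction == "random":
        direction = "zoom_in" if np.random.default_rng(seed).random() < 0.5 else "zoom_out"
    return 1.0 + lam if direction == "zoom_in" else 1.0 / (1.0 + lam)


def radial_field(patch_size: int, beta: float, epsilon: float = EPSILON) -> DeformationField:
    """Build the radial deformation field for an s-by-s patch.

    Coordinates are 0-based pixel centers, so the patch center is
    ``((s-1)/2, (s-1)/2)`` and the deformation radius is ``R = s/2``
    (24 for the default 48-pixel patches).
    """
    if patch_size < 2:
        raise ValueError("patch size must be >= 2")
    if beta <= 0:
        raise ValueError("beta must be > 0")
    s = patch_size
    radius = s / 2.0
    cy = cx = (s - 1) / 2.0
    y, x = np.mgrid[0:s, 0:s].astype(np.float64)
    r = np.hypot(x - cx, y - cy)
    r_norm = r / radius
    r_prime = radius * r_norm**beta
    scale = r_prime / (r + epsilon)
    inside = r <= radius
    dx = np.where(inside, cx + scale * (x - cx) - x, 0.0)
    dy = np.where(inside, cy + scale * (y - cy) - y, 0.0)
    return DeformationField(delta_x=dx, delta_y=dy, beta=beta, radius=radius, epsilon=epsilon)


def warp_label(
    label_window: np.ndarray, fld: DeformationField, interpolation: str = "nearest"
) -> np.ndarray:
    """Resample a binary label window through a deformation field.

    ``out(p) = label(p')`` with nearest-neighbor sampling by default, which
    preserves binarity without a thresholding rule (``interpolation=
    "bilinear"`` thresholds the interpolated value at 0.5 instead). Source
    points falling outside the window read background 0.
    """
    label_window = np.asarray(label_window)
    s = label_window.shape[0]
    if label_window.shape != fld.delta_x.shape:
        raise ValueError(
            f"label window {label_window.shape} does not match field {fld.delta_x.shape}"
        )
    if not np.isin(np.unique(label_window), [0, 1]).all():
        raise ValueError("label window is not binary")
    y, x = np.mgrid[0:s, 0:s].astype(np.float64)
    src_x = x + fld.delta_x
    src_y = y + fld.delta_y
    if interpolation == "bilinear":
        sampled = ndimage.map_coordinates(
            label_window.astype(np.float64), [src_y, src_x], order=1, mode="constant", cval=0.0
        )
        return (sampled > 0.5).astype(np.uint8)
    ix = np.floor(src_x + 0.5).astype(np.int64)
    iy = np.floor(src_y + 0.5).astype(np.int64)
    valid = (ix >= 0) & (ix < s) & (iy >= 0) & (iy < s)
    out = np.zeros_like(label_window, dtype=np.uint8)
    out[valid] = label_window[iy[valid], ix[valid]]
    return out


def corrupt_image(image: np.ndarray, kind: str, lam: float, seed: int = 0) -> np.ndarray:
    """Apply one of the baseline image-level corruptions at strength lam.

    gaussian: additive zero-mean noise with sigma = lam * 25 gray levels;
    lowres: bilinear downsample by (1 + 3*lam) and upsample back;
    uniform_blur: box blur with kernel width 1 + 2*round(4*lam);
    fovea_blur: the same box blur confined (with a linear radial ramp) to
    the central disc of radius min(H, W)/2.
    lam = 0 returns the image unchanged for every kind.
    """
    if kind not in ("gaussian", "lowres", "uniform_blur", "fovea_blur"):
        raise ValueError(f"unknown corruption kind {kind!r}")
    if not 0.0 <= lam <= 1.0:
        raise ValueError("corruption strength must lie in [0, 1]")
    image = np.asarray(image)
    if lam == 0.0:
        return image.copy()
    img = image.astype(np.float64)
    if kind == "gaussian":
        rng = np.random.default_rng(seed)
        out = img + rng.normal(0.0, lam * SIGMA_MAX, size=img.shape)
    elif kind == "lowres":
        factor = 1.0 + 3.0 * lam
        small = ndimage.zoom(img, 1.0 / factor, order=1, mode="nearest")
        back = ndimage.zoom(small, np.array(img.shape) / np.array(small.shape), order=1, mode="nearest")
        out = back[: img.shape[0], : img.shape[1]]
        if out.shape != img.shape:  # zoom can undershoot by one row/col
            pad = [(0, img.shape[i] - out.shape[i]) for i in range(2)]
            out = np.pad(out, pad, mode="edge")
    else:
        width = int(1 + 2 * round(4 * lam))
        blurred = ndimage.uniform_filter(img, size=width, mode="nearest")
        if kind == "uniform_blur":
            out = blurred
        else:  # fovea_blur
            h, w = img.shape
            radius = min(h, w) / 2.0
            y, x = np.mgrid[0:h, 0:w].astype(np.float64)
            r = np.hypot(x - (w - 1) / 2.0, y - (h - 1) / 2.0)
            weight = np.clip(1.0 - r / radius, 0.0, 1.0)
            out = weight * blurred + (1.0 - weight) * img
    return np.floor(out + 0.5).clip(0, 255).astype(image.dtype)


def mix_labels(
    patchset: PatchSet,
    lam: float,
    rho: float,
    direction_mode: str = "zoom_in",
    seed: int = 0,
) -> PatchSet:
    """Deform the labels of a seeded random fraction rho of the patches.

    Exactly ``round(rho * N)`` patches (chosen uniformly without
    replacement) get their label window warped with a per-patch beta from
    :func:`beta_from_level`; the rest keep clean labels. The returned set
    carries per-patch noise flags.
    """
    if not 0.0 <= rho <= 1.0:
        raise ValueError("noise ratio must lie in [0, 1]")
    n = len(patchset)
    n_noisy = int(np.floor(rho * n + 0.5))
    rng = np.random.default_rng(derive_seed(seed, "mix-select"))
    chosen = rng.choice(n, size=n_noisy, replace=False)
    flags = np.zeros(n, dtype=bool)
    flags[chosen] = True
    labels = patchset.labels.copy()
    s = patchset.patch_size
    field_cache: dict[float, DeformationField] = {}
    for i in chosen:
        beta = beta_from_level(lam, direction_mode, derive_seed(seed, "beta", int(i)))
        fld = field_cache.get(beta)
        if fld is None:
            fld = field_cache[beta] = radial_field(s, beta)
        labels[i] = warp_label(patchset.labels[i], fld)
    return patchset.with_labels(labels, noisy=flags)


def remove_noisy(patchset: PatchSet) -> PatchSet:
    """Keep only the patches whose labels were left clean by mix_labels."""
    if patchset.noisy is None:
        raise ValueError("patch set carries no noise flags")
    return patchset.subset(~patchset.noisy)
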