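"""Fundus image preprocessing: grayscale, z-score, CLAHE, gamma adjustment.

The enhancement chain converts a color fundus photograph into a
contrast-enhanced single-channel 8-bit image:

1. grayscale conversion (ITU-R 601 luma by default; the green channel —
   where fundus vessel contrast concentrates — as an option),
2. z-score normalization ``I' = (I - mu) / sigma`` over all pixels,
3. an affine min-max rescale back onto [0, 255] (CLAHE operates on 8-bit
   histograms, so the real-valued normalized raster must be re-quantized),
4. contrast-limited adaptive histogram equalization with clip limit ``c``
   and a ``t x t`` tile grid,
5. gamma adjustment ``J = 255 * (I / 255)^(1/gamma)`` with gamma > 1
   brightening dark areas.

Wherever intensities are quantized, rounding is half-away-from-zero, stated
here once for cross-platform bit-stability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from vesselnoise.dataio import FundusSample, with_image

LUMA_WEIGHTS = (0.299, 0.587, 0.114)  # ITU-R 601


class DegenerateImageError(ValueError):
    """Raised for constant images, whose statistics poison later stages."""


def round_half_away(x: np.ndarray) -> np.ndarray:
    """Round half away from zero (all preprocessing values are >= 0)."""
    return np.floor(np.asarray(x) + 0.5)


@dataclass
class PreprocessConfig:
    grayscale_mode: str = "luma"  # or "green_channel"
    gamma: float = 1.6
    clahe_clip: float = 2.0
    clahe_tiles: int = 8
    fov_only: bool = False  # restrict the z-score statistics to FOV pixels

    def validate(self) -> "PreprocessConfig":
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")
        if self.clahe_clip <= 0:
            raise ValueError("clahe clip limit must be > 0")
        if self.clahe_tiles < 1:
            raise ValueError("clahe tile grid must be >= 1")
        if self.grayscale_mode not in ("luma", "green_channel"):
            raise ValueError(f"unknown grayscale mode {self.grayscale_mode!r}")
        return self


def to_grayscale(image: np.ndarray, mode: str = "luma") -> np.ndarray:
    """Convert a 1- or 3-channel 8-bit image to a single channel.

    1-channel input passes through unchanged.
    """
    image = np.asarray(image)
    if image.ndim == 2:
        return image.astype(np.uint8)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected 1 or 3 channels, got shape {image.shape}")
    if mode == "green_channel":
        return image[:, :, 1].astype(np.uint8)
    if mode == "luma":
        w = np.asarray(LUMA_WEIGHTS)
        gray = image.astype(np.float64) @ w
        return round_half_away(gray).clip(0, 255).astype(np.uint8)
    raise ValueError(f"unknown grayscale mode {mode!r}")


def zscore_normalize(gray: np.ndarray, where: np.ndarray | None = None) -> np.ndarray:
    """Standardize pixel values to mean 0 and population standard deviation 1.

    ``where`` optionally restricts the statistics (not the transform) to a
    boolean region such as the field of view.
    """
    gray = np.asarray(gray, dtype=np.float64)
    if gray.size == 0:
        raise ValueError("empty raster")
    vals = gray[where.astype(bool)] if where is not None else gray
    mu = vals.mean()
    sigma = vals.std()  # population standard deviation
    if sigma == 0:
        raise DegenerateImageError("constant image: standard deviation is zero")
    return (gray - mu) / sigma


def rescale_to_8bit(raster: np.ndarray) -> np.ndarray:
    """Affine min-max map onto [0, 255], rounded half away from zero."""
    raster = np.asarray(raster, dtype=np.float64)
    lo, hi = raster.min(), raster.max()
    if hi == lo:
        raise DegenerateImageError("constant raster cannot be min-max rescaled")
    scaled = (raster - lo) * (255.0 / (hi - lo))
    return round_half_away(scaled).clip(0, 255).astype(np.uint8)


def _tile_edges(n: int, t: int) -> np.ndarray:
    """Split ``n`` pixels into ``t`` near-equal contiguous tiles; returns t+1 edges."""
    return np.round(np.linspace(0, n, t + 1)).astype(int)


def _tile_lut(tile: np.ndarray, clip: float) -> np.ndarray:
    """Clipped-histogram equalization mapping for one tile.

    The clip limit caps each of the 256 bins at ``clip`` times the mean bin
    height; the clipped excess is redistributed uniformly over all bins in a
    single pass, conserving total histogram mass.
    """
    area = tile.size
    hist = np.bincount(tile.ravel(), minlength=256).astype(np.float64)
    limit = max(clip * area / 256.0, 1.0)
    excess = np.maximum(hist - limit, 0.0).sum()
    hist = np.minimum(hist, limit) + excess / 256.0
    cdf = np.cumsum(hist)
    return round_half_away(cdf * (255.0 / area)).clip(0, 255).astype(np.uint8)


def clahe(gray: np.ndarray, clip: float = 2.0, tiles: int = 8) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization on an 8-bit raster.

    Per-tile clipped histogram equalization with bilinear blending between
    the mappings of adjacent tiles (interpolated between tile centers,
    clamped at the borders).
    """
    gray = np.asarray(gray)
    if gray.dtype != np.uint8:
        raise ValueError("clahe expects an 8-bit raster")
    h, w = gray.shape
    if h < tiles or w < tiles:
        raise ValueError(f"image {gray.shape} smaller than the {tiles}x{tiles} tile grid")
    ye = _tile_edges(h, tiles)
    xe = _tile_edges(w, tiles)
    luts = np.empty((tiles, tiles, 256), dtype=np.uint8)
    for i in range(tiles):
        for j in range(tiles):
            luts[i, j] = _tile_lut(gray[ye[i] : ye[i + 1], xe[j] : xe[j + 1]], clip)

    def axis_interp(coords: np.ndarray, edges: np.ndarray):
        centers = (edges[:-1] + edges[1:]) / 2.0 - 0.5
        i1 = np.searchsorted(centers, coords)  # first center >= coord
        i0 = np.clip(i1 - 1, 0, tiles - 1)
        i1 = np.clip(i1, 0, tiles - 1)
        span = centers[i1] - centers[i0]
        frac = np.where(span > 0, (coords - centers[i0]) / np.where(span > 0, span, 1.0), 0.0)
        return i0, i1, np.clip(frac, 0.0, 1.0)

    r0, r1, fy = axis_interp(np.arange(h, dtype=np.float64), ye)
    c0, c1, fx = axis_interp(np.arange(w, dtype=np.float64), xe)
    fy = fy[:, None]
    fx = fx[None, :]
    v00 = luts[r0[:, None], c0[None, :], gray].astype(np.float64)
    v01 = luts[r0[:, None], c1[None, :], gray].astype(np.float64)
    v10 = luts[r1[:, None], c0[None, :], gray].astype(np.float64)
    v11 = luts[r1[:, None], c1[None, :], gray].astype(np.float64)
    out = (1 - fy) * ((1 - fx) * v00 + fx * v01) + fy * ((1 - fx) * v10 + fx * v11)
    return round_half_away(out).clip(0, 255).astype(np.uint8)


def gamma_adjust(gray: np.ndarray, gamma: float) -> np.ndarray:
    """Global tone mapping ``J = 255 * (I / 255)^(1/gamma)``.

    Endpoints are fixed (0 -> 0, 255 -> 255); gamma > 1 brightens dark
    regions, enhancing their contrast.
    """
    if gamma <= 0:
        raise ValueError("gamma must be > 0")
    gray = np.asarray(gray)
    if gray.dtype != np.uint8:
        raise ValueError("gamma_adjust expects an 8-bit raster")
    levels = np.arange(256, dtype=np.float64)
    lut = round_half_away(255.0 * (levels / 255.0) ** (1.0 / gamma)).astype(np.uint8)
    return lut[gray]


def preprocess(sample: FundusSample, cfg: PreprocessConfig | None = None) -> FundusSample:
    """Run the full enhancement chain on one sample; masks are untouched."""
    cfg = (cfg or PreprocessConfig()).validate()
    stages = [
        ("to_grayscale", lambda img: to_grayscale(img, cfg.grayscale_mode)),
        (
            "zscore_normalize",
            lambda img: zscore_normalize(img, sample.fov_mask if cfg.fov_only else None),
        ),
        ("rescale_to_8bit", rescale_to_8bit),
        ("clahe", lambda img: clahe(img, cfg.clahe_clip, cfg.clahe_tiles)),
        ("gamma_adjust", lambda img: gamma_adjust(img, cfg.gamma)),
    ]
    img = sample.image
    for name, fn in stages:
        try:
            img = fn(img)
        except Exception as exc:
            raise type(exc)(f"preprocess stage {name!r}: {exc}") from exc
    return with_image(sample, img)
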