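"""Reading and writing fundus samples, masks, manifests and probability maps.

Datasets are described by a flat CSV manifest with columns
``sample_id,image,vessel_mask,fov_mask,split`` whose paths are resolved
relative to the manifest's own directory (DRIVE-style datasets ship as
parallel folders; the manifest is the minimal abstraction over them).
Masks of any bit depth are binarized (nonzero -> 1) on load; vessel pixels
falling outside the field of view are repaired by intersection and logged.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import imageio.v3 as iio
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MANIFEST_COLUMNS = ["sample_id", "image", "vessel_mask", "fov_mask", "split"]


class ManifestError(ValueError):
    """Raised when a dataset manifest is malformed or references missing files."""


@dataclass
class FundusSample:
    """One fundus photograph with its vessel annotation and field-of-view mask.

    ``image`` is an 8-bit 2D (grayscale) or HxWx3 (RGB) raster; both masks
    are binary {0, 1} uint8 rasters of the same height and width.
    """

    sample_id: str
    image: np.ndarray
    vessel_mask: np.ndarray
    fov_mask: np.ndarray
    source_path: str = ""

    def validate(self) -> "FundusSample":
        h, w = self.image.shape[:2]
        for name, mask in (("vessel_mask", self.vessel_mask), ("fov_mask", self.fov_mask)):
            if mask.shape != (h, w):
                raise ValueError(
                    f"sample {self.sample_id!r}: {name} shape {mask.shape} "
                    f"does not match image shape {(h, w)}"
                )
            vals = np.unique(mask)
            if not np.isin(vals, [0, 1]).all():
                raise ValueError(f"sample {self.sample_id!r}: {name} is not binary")
        if np.any(self.vessel_mask > self.fov_mask):
            raise ValueError(f"sample {self.sample_id!r}: vessel pixels outside the FOV")
        return self


@dataclass
class ManifestEntry:
    sample_id: str
    image: Path
    vessel_mask: Path
    fov_mask: Optional[Path]
    split: str


@dataclass
class DatasetManifest:
    """Ordered list of samples with their file locations and train/test split."""

    entries: list[ManifestEntry] = field(default_factory=list)

    def split(self, which: str) -> list[ManifestEntry]:
        return [e for e in self.entries if e.split == which]

    def __len__(self) -> int:
        return len(self.entries)


def load_manifest(path: str | os.PathLike) -> DatasetManifest:
    """Load and validate a CSV dataset manifest.

    Raises :class:`ManifestError` naming the offending sample on missing
    files or duplicate sample ids.
    """
    path = Path(path)
    if not path.exists():
        raise ManifestError(f"manifest not found: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing_cols = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ManifestError(f"manifest {path} missing columns {missing_cols}")
    root = path.parent
    entries = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        sid = row["sample_id"]
        if sid in seen:
            raise ManifestError(f"duplicate sample_id {sid!r} in manifest {path}")
        seen.add(sid)
        if row["split"] not in ("train", "test"):
            raise ManifestError(f"sample {sid!r}: unknown split {row['split']!r}")
        img = root / row["image"]
        ves = root / row["vessel_mask"]
        fov = root / row["fov_mask"] if row["fov_mask"] else None
        for role, p in (("image", img), ("vessel_mask", ves), ("fov_mask", fov)):
            if p is not None and not p.exists():
                raise ManifestError(f"sample {sid!r}: {role} file not found: {p}")
        entries.append(ManifestEntry(sid, img, ves, fov, row["split"]))
    return DatasetManifest(entries)


def save_manifest(manifest: DatasetManifest, path: str | os.PathLike) -> None:
    """Write a manifest CSV with paths stored relative to the CSV's directory."""
    path = Path(path)
    root = path.parent
    rows = []
    for e in manifest.entries:
        rows.append(
            {
                "sample_id": e.sample_id,
                "image": os.path.relpath(e.image, root),
                "vessel_mask": os.path.relpath(e.vessel_mask, root),
                "fov_mask": os.path.relpath(e.fov_mask, root) if e.fov_mask else "",
                "split": e.split,
            }
        )
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(path, index=False)


def _read_raster(path: Path) -> np.ndarray:
    arr = np.asarray(iio.imread(path))
    if arr.ndim == 4:  # animated container (e.g. GIF): first frame
        arr = arr[0]
    if arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha
        arr = arr[:, :, :3]
    return arr


def _read_mask(path: Path) -> np.ndarray:
    arr = _read_raster(path)
    if arr.ndim == 3:
        # paletted GIFs / RGB-encoded masks: any nonzero channel counts
        arr = arr.max(axis=2)
    if arr.ndim != 2:
        raise ValueError(f"mask {path} is not decodable to a 2D raster")
    return (arr > 0).astype(np.uint8)


def load_sample(entry: ManifestEntry) -> FundusSample:
    """Load one manifest entry into a validated :class:`FundusSample`.

    Masks are binarized (nonzero -> 1). A missing FOV mask is replaced by a
    full-frame FOV. Vessel pixels outside the FOV are removed with a warning.
    """
    image = _read_raster(entry.image)
    vessel = _read_mask(entry.vessel_mask)
    h, w = image.shape[:2]
    if entry.fov_mask is not None:
        fov = _read_mask(entry.fov_mask)
    else:
        logger.warning("sample %r: no FOV mask; substituting full-frame FOV", entry.sample_id)
        fov = np.ones((h, w), dtype=np.uint8)
    if vessel.shape != (h, w) or fov.shape != (h, w):
        raise ValueError(
            f"sample {entry.sample_id!r}: mask shapes {vessel.shape}/{fov.shape} "
            f"do not match image shape {(h, w)}"
        )
    outside = int(np.sum((vessel == 1) & (fov == 0)))
    if outside:
        logger.warning(
            "sample %r: %d vessel pixels outside the FOV removed by intersection",
            entry.sample_id,
            outside,
        )
        vessel = vessel * fov
    return FundusSample(
        sample_id=entry.sample_id,
        image=image,
        vessel_mask=vessel,
        fov_mask=fov,
        source_path=str(entry.image),
    ).validate()


def load_dataset(manifest: DatasetManifest, split: Optional[str] = None) -> list[FundusSample]:
    entries = manifest.entries if split is None else manifest.split(split)
    return [load_sample(e) for e in entries]


def save_mask(mask: np.ndarray, path: str | os.PathLike) -> None:
    """Write a binary mask as an 8-bit PNG with values {0, 255}."""
    vals = np.unique(mask)
    if not np.isin(vals, [0, 1]).all():
        raise ValueError("mask is not binary")
    iio.imwrite(Path(path), (mask.astype(np.uint8) * 255))


def save_image(image: np.ndarray, path: str | os.PathLike) -> None:
    iio.imwrite(Path(path), np.asarray(image, dtype=np.uint8))


def save_probability_map(prob: np.ndarray, path: str | os.PathLike) -> None:
    """Store a probability raster as a 16-bit PNG (quantization step 1/65535)."""
    prob = np.asarray(prob, dtype=np.float64)
    if prob.min() < 0.0 or prob.max() > 1.0:
        raise ValueError("probability map values must lie in [0, 1]")
    quant = np.floor(prob * 65535.0 + 0.5).astype(np.uint16)
    iio.imwrite(Path(path), quant)


def load_probability_map(path: str | os.PathLike) -> np.ndarray:
    arr = np.asarray(iio.imread(Path(path)), dtype=np.float64)
    return arr / 65535.0


def with_image(sample: FundusSample, image: np.ndarray) -> FundusSample:
    """Return a copy of ``sample`` with a replaced image (masks untouched)."""
    return replace(sample, image=image)
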