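"""Seeded synthetic fundus-like images with exact vessel ground truth.

Each sample emulates the salient properties of real fundus photographs: a
circular field of view on a dark surround, inhomogeneous (radially falling)
illumination with background texture, and a branching vessel tree rendered
darker than the background, whose widths taper from ~8 px trunks down to
1-2 px capillaries. Centerlines are recursive midpoint-displaced segments;
rasterization thresholds the distance to the centerline so widths are
exact in pixels, and the binary vessel mask is the exact rasterized
support. An optional central light reflex (bright thin ridge along wide
trunks) can be enabled to emulate hand-held pediatric acquisitions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from vesselnoise._seed import derive_seed
from vesselnoise.dataio import (
    DatasetManifest,
    FundusSample,
    ManifestEntry,
    load_manifest,
    save_image,
    save_manifest,
    save_mask,
)


@dataclass
class SynthConfig:
    image_size: tuple[int, int] = (128, 128)
    n_trees: int = 2
    trunk_width: float = 8.0
    min_width: float = 1.0
    branch_decay: float = 0.55
    vessel_contrast: float = 60.0
    illumination_gradient: float = 0.35
    background_noise_sd: float = 5.0
    fov_margin: int = 4
    light_reflex: bool = False
    seed: int = 0

    def validate(self) -> "SynthConfig":
        if self.min_width < 1 or self.trunk_width < self.min_width:
            raise ValueError("widths must satisfy trunk_width >= min_width >= 1")
        if not 0.0 < self.branch_decay < 1.0:
            raise ValueError("branch_decay must lie in (0, 1)")
        if min(self.image_size) < 96:
            raise ValueError("image must be at least twice the 48-pixel patch size")
        return self


def _midpoint_polyline(p0, p1, rng, roughness=0.18, depth=4):
    """Jittered polyline between two points (midpoint displacement)."""
    pts = [np.asarray(p0, dtype=float), np.asarray(p1, dtype=float)]
    rough = roughness
    for _ in range(depth):
        new = [pts[0]]
        for a, b in zip(pts[:-1], pts[1:]):
            mid = (a + b) / 2.0
            seg = b - a
            norm = np.hypot(*seg)
            if norm > 0:
                normal = np.array([-seg[1], seg[0]]) / norm
                mid = mid + normal * rng.normal(0.0, rough)
            new += [mid, b]
        pts = new
        rough *= 0.5
    return np.array(pts)


def _stamp_segment(canvas: np.ndarray, polyline: np.ndarray, width: float) -> None:
    """Mark every pixel within width/2 of the polyline (distance threshold)."""
    h, w = canvas.shape
    radius = width / 2.0
    # densify so consecutive samples are < 0.5 px apart
    for a, b in zip(polyline[:-1], polyline[1:]):
        steps = max(int(np.ceil(np.hypot(*(b - a)) / 0.5)), 1)
        ts = np.linspace(0.0, 1.0, steps + 1)
        for t in ts:
            cy, cx = a + t * (b - a)
            r = int(math.ceil(radius))
            y0, y1 = max(int(cy) - r, 0), min(int(cy) + r + 1, h)
            x0, x1 = max(int(cx) - r, 0), min(int(cx) + r + 1, w)
            if y0 >= y1 or x0 >= x1:
                continue
            yy, xx = np.mgrid[y0:y1, x0:x1]
            canvas[y0:y1, x0:x1] |= (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2


def _grow_tree(mask, reflex, start, direction, width, cfg: SynthConfig, rng, depth=0):
    if width < cfg.min_width or depth > 6:
        return
    h, w = mask.shape
    length = rng.uniform(0.10, 0.18) * min(h, w) * (0.85**depth)
    end = np.asarray(start) + np.asarray(direction) * length
    poly = _midpoint_polyline(start, end, rng, roughness=0.08 * length)
    _stamp_segment(mask, poly, width)
    if cfg.light_reflex and width >= 0.6 * cfg.trunk_width:
        _stamp_segment(reflex, poly, 1.0)
    # two children, rotated away from the parent direction
    for sign in (-1.0, 1.0):
        angle = sign * rng.uniform(0.3, 0.8)
        c, s = math.cos(angle), math.sin(angle)
        ndir = np.array([c * direction[0] - s * direction[1], s * direction[0] + c * direction[1]])
        ndir /= np.linalg.norm(ndir)
        child_width = width * cfg.branch_decay * rng.uniform(0.85, 1.1)
        _grow_tree(mask, reflex, end, ndir, child_width, cfg, rng, depth + 1)


def generate_sample(cfg: SynthConfig | None = None, sample_id: str = "synth") -> FundusSample:
    """Generate one synthetic fundus sample; deterministic given the seed."""
    cfg = (cfg or SynthConfig()).validate()
    rng = np.random.default_rng(cfg.seed)
    h, w = cfg.image_size
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    fov_radius = min(h, w) / 2.0 - cfg.fov_margin
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    r = np.hypot(yy - cy, xx - cx)
    fov = (r <= fov_radius).astype(np.uint8)

    vessel = np.zeros((h, w), dtype=bool)
    reflex = np.zeros((h, w), dtype=bool)
    for _ in range(cfg.n_trees):
        theta = rng.uniform(0.0, 2.0 * math.pi)
        start = np.array([cy + 0.85 * fov_radius * math.sin(theta),
                          cx + 0.85 * fov_radius * math.cos(theta)])
        inward = np.array([cy - start[0], cx - start[1]])
        inward /= np.linalg.norm(inward)
        jitter = rng.uniform(-0.5, 0.5)
        c, s = math.cos(jitter), math.sin(jitter)
        direction = np.array([c * inward[0] - s * inward[1], s * inward[0] + c * inward[1]])
        _grow_tree(vessel, reflex, start, direction, cfg.trunk_width, cfg, rng)
    vessel &= fov.astype(bool)
    reflex &= vessel

    # background: bright center with a radial illumination falloff + texture
    base = 185.0
    illum = base * (1.0 - cfg.illumination_gradient * (r / fov_radius) ** 2)
    texture = rng.normal(0.0, cfg.background_noise_sd, size=(h, w))
    image = illum + texture
    image[vessel] -= cfg.vessel_contrast
    if cfg.light_reflex:
        image[reflex] += 0.7 * cfg.vessel_contrast
    image[fov == 0] = 8.0 + texture[fov == 0]
    image = np.clip(np.floor(image + 0.5), 0, 255).astype(np.uint8)

    return FundusSample(
        sample_id=sample_id,
        image=image,
        vessel_mask=vessel.astype(np.uint8),
        fov_mask=fov,
    ).validate()


def generate_dataset(cfg: SynthConfig, n_train: int, n_test: int) -> tuple[list, list]:
    """In-memory train/test sample lists with per-sample derived seeds."""
    cfg = cfg.validate()
    train, test = [], []
    for i in range(n_train + n_test):
        sub = SynthConfig(**{**cfg.__dict__, "seed": derive_seed(cfg.seed, "sample", i)})
        split = "train" if i < n_train else "test"
        sid = f"{split}_{i if i < n_train else i - n_train:02d}"
        (train if i < n_train else test).append(generate_sample(sub, sample_id=sid))
    return train, test


def write_dataset(
    cfg: SynthConfig, n_train: int, n_test: int, out_dir
) -> DatasetManifest:
    """Write a dataio-compatible synthetic dataset (images, masks, FOVs and a
    manifest CSV) and return the reloaded, validated manifest."""
    if n_train < 1 or n_test < 1:
        raise ValueError("both splits must be non-empty")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    train, test = generate_dataset(cfg, n_train, n_test)
    entries = []
    for sample, split in [(s, "train") for s in train] + [(s, "test") for s in test]:
        img = out / f"{sample.sample_id}_image.png"
        ves = out / f"{sample.sample_id}_vessel.png"
        fov = out / f"{sample.sample_id}_fov.png"
        save_image(sample.image, img)
        save_mask(sample.vessel_mask, ves)
        save_mask(sample.fov_mask, fov)
        entries.append(ManifestEntry(sample.sample_id, img, ves, fov, split))
    manifest_path = out / "manifest.csv"
    save_manifest(DatasetManifest(entries), manifest_path)
    return load_manifest(manifest_path)
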