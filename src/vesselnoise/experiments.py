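"""Training, evaluation metrics, and the noise sweep harnesses.

Metrics are the standard confusion-matrix family — accuracy, specificity,
sensitivity (recall), precision, F1 — plus the ROC AUC of the probability
map, all computed over field-of-view pixels only (the DRIVE community
convention, matching the FOV discipline used when sampling patches). The
sweeps retrain one fresh seeded model per condition: noise-level (deform
all training labels at each level), noise-ratio (level x ratio grid via
label mixing), noise-type (image-level baseline corruptions vs the
non-linear label deformation), and the cleaning comparison (full noisy
pool vs the clean subset).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from vesselnoise._nn import SGD, softmax_cross_entropy
from vesselnoise._seed import derive_seed
from vesselnoise.config import ExperimentConfig, TrainConfig
from vesselnoise.dataio import FundusSample, with_image
from vesselnoise.model import UNet, predict_patches
from vesselnoise.noise import NoiseSpec, corrupt_image, mix_labels, remove_noisy
from vesselnoise.patches import (
    PatchSet,
    concat_patchsets,
    extract_training_patches,
    recombine,
    rotate_augment,
    tile_test_patches,
)
from vesselnoise.preprocessing import preprocess

logger = logging.getLogger(__name__)

METRIC_COLUMNS = ["tp", "fp", "tn", "fn", "acc", "sp", "sn", "precision", "f1", "auc"]


@dataclass
class MetricReport:
    """Confusion counts and derived scores for one evaluated image."""

    tp: int
    fp: int
    tn: int
    fn: int
    acc: float
    sp: float
    sn: float
    precision: float
    f1: float
    auc: float
    n_pixels: int
    condition: Optional[NoiseSpec] = None
    flags: list[str] = field(default_factory=list)

    def as_row(self) -> dict:
        row = {c: getattr(self, c) for c in METRIC_COLUMNS}
        row["n_pixels"] = self.n_pixels
        if self.condition is not None:
            row["noise_level"] = self.condition.noise_level
            row["noise_ratio"] = self.condition.noise_ratio
            row["corruption"] = self.condition.corruption
        return row


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def _to_batch(images: np.ndarray, labels: np.ndarray):
    x = images.astype(np.float32)
    if images.dtype == np.uint8:
        x = x / 255.0
    x = x[:, None]
    lab = labels.astype(np.float32)
    y = np.stack([1.0 - lab, lab], axis=1)
    return x, y


def train(model: UNet, patchset: PatchSet, cfg: TrainConfig | None = None) -> list[float]:
    """SGD training over shuffled mini-batches; returns the per-epoch mean loss.

    The shuffle and the dropout stream are both derived from ``cfg.seed``,
    so the loss trace is reproducible on one platform.
    """
    cfg = (cfg or TrainConfig()).validate()
    if len(patchset) == 0:
        raise ValueError("cannot train on an empty patch set")
    optimizer = SGD(lr=cfg.learning_rate, momentum=cfg.momentum)
    model.reseed_dropout(derive_seed(cfg.seed, "dropout"))
    layers = model.param_layers()
    trace: list[float] = []
    n = len(patchset)
    for epoch in range(cfg.epochs):
        rng = np.random.default_rng(derive_seed(cfg.seed, "shuffle", epoch))
        perm = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = perm[start : start + cfg.batch_size]
            x, y = _to_batch(patchset.images[idx], patchset.labels[idx])
            logits = model.forward(x, train=True)
            loss, dlogits = softmax_cross_entropy(logits, y)
            model.backward(dlogits)
            optimizer.step(layers)
            losses.append(loss)
        trace.append(float(np.mean(losses)))
    return trace


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


def binarize(prob_map: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Threshold a probability map: strictly greater than ``threshold`` is
    vessel (1); ties resolve to background for determinism."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    prob_map = np.asarray(prob_map)
    if prob_map.min() < 0.0 or prob_map.max() > 1.0:
        raise ValueError("probability map values must lie in [0, 1]")
    return (prob_map > threshold).astype(np.uint8)


def confusion_counts(pred: np.ndarray, truth: np.ndarray, fov: np.ndarray):
    """(tp, fp, tn, fn) over FOV pixels only."""
    if not (pred.shape == truth.shape == fov.shape):
        raise ValueError("prediction, truth and FOV shapes must match")
    m = fov.astype(bool)
    p = pred[m].astype(bool)
    t = truth[m].astype(bool)
    tp = int(np.sum(p & t))
    fp = int(np.sum(p & ~t))
    tn = int(np.sum(~p & ~t))
    fn = int(np.sum(~p & t))
    return tp, fp, tn, fn


def _safe_div(num: float, den: float, flags: list[str], name: str) -> float:
    if den == 0:
        flags.append(f"degenerate:{name}")
        return 0.0
    return num / den


def compute_metrics(
    counts,
    prob_map: Optional[np.ndarray] = None,
    truth: Optional[np.ndarray] = None,
    fov: Optional[np.ndarray] = None,
    condition: Optional[NoiseSpec] = None,
) -> MetricReport:
    """Derive Acc/Sp/Sn/Precision/F1 from counts and AUC from the map.

    Degenerate denominators (e.g. no predicted positives) yield 0 with a
    flag rather than an error; a single-class truth leaves AUC as NaN with
    an ``auc_undefined`` flag.
    """
    tp, fp, tn, fn = (int(c) for c in counts)
    flags: list[str] = []
    n = tp + fp + tn + fn
    acc = _safe_div(tp + tn, n, flags, "acc")
    sp = _safe_div(tn, tn + fp, flags, "sp")
    sn = _safe_div(tp, tp + fn, flags, "sn")
    precision = _safe_div(tp, tp + fp, flags, "precision")
    f1 = _safe_div(2.0 * precision * sn, precision + sn, flags, "f1")
    auc = float("nan")
    if prob_map is not None and truth is not None and fov is not None:
        m = fov.astype(bool)
        t = truth[m].astype(int)
        if t.min() == t.max():
            flags.append("auc_undefined")
        else:
            auc = float(roc_auc_score(t, prob_map[m]))
    return MetricReport(
        tp=tp, fp=fp, tn=tn, fn=fn,
        acc=acc, sp=sp, sn=sn, precision=precision, f1=f1, auc=auc,
        n_pixels=n, condition=condition, flags=flags,
    )


def predict_full(model: UNet, sample: FundusSample, cfg: ExperimentConfig) -> np.ndarray:
    """Tile a (preprocessed) image, predict every patch, and average the
    overlaps back into a full-frame vessel-probability map."""
    layout, tiles = tile_test_patches(sample.image, cfg.sampling)
    probs = predict_patches(model, tiles)
    return recombine(probs, layout)


def evaluate_sample(
    model: UNet,
    sample: FundusSample,
    cfg: ExperimentConfig | None = None,
    condition: Optional[NoiseSpec] = None,
) -> MetricReport:
    """Full inference chain on one preprocessed sample: tile, predict,
    recombine, threshold, score inside the FOV."""
    cfg = (cfg or ExperimentConfig()).validate()
    prob = predict_full(model, sample, cfg)
    pred = binarize(prob, cfg.threshold)
    counts = confusion_counts(pred, sample.vessel_mask, sample.fov_mask)
    return compute_metrics(counts, prob, sample.vessel_mask, sample.fov_mask, condition)


# ---------------------------------------------------------------------------
# condition runner and sweeps
# ---------------------------------------------------------------------------


def prepare_patches(
    train_samples: Sequence[FundusSample], cfg: ExperimentConfig, seed: int
) -> PatchSet:
    """Extract (and optionally rotation-augment) the pooled training patches."""
    sets = [
        extract_training_patches(s, cfg.sampling, seed=derive_seed(seed, "extract", s.sample_id))
        for s in train_samples
    ]
    pool = concat_patchsets(sets)
    if cfg.rotate:
        pool = rotate_augment(pool)
    return pool


def run_condition(
    train_samples: Sequence[FundusSample],
    test_samples: Sequence[FundusSample],
    cfg: ExperimentConfig,
    spec: NoiseSpec,
    seed: int,
    patches: Optional[PatchSet] = None,
    keep_clean_only: bool = False,
):
    """Train one fresh model under a corruption condition and evaluate it.

    Samples are expected preprocessed. ``nonlinear`` corrupts label patches
    via the radial deformation; the image-level kinds corrupt the training
    images before extraction and keep labels clean; ``none`` is the clean
    baseline. ``keep_clean_only`` drops the noisy patches after mixing (the
    cleaning-comparison arm). Returns ``(model, [MetricReport per test
    sample], patchset_used)``.
    """
    spec = spec.validate()
    cfg = cfg.validate()
    if spec.corruption in ("gaussian", "lowres", "uniform_blur", "fovea_blur"):
        train_samples = [
            with_image(
                s,
                corrupt_image(
                    s.image, spec.corruption, spec.noise_level,
                    seed=derive_seed(seed, "corrupt", s.sample_id),
                ),
            )
            for s in train_samples
        ]
        patches = None  # images changed; any pre-extracted pool is stale
    if patches is None:
        patches = prepare_patches(train_samples, cfg, seed)
    if spec.corruption == "nonlinear" and spec.noise_ratio > 0:
        patches = mix_labels(
            patches,
            spec.noise_level,
            spec.noise_ratio,
            spec.direction_mode,
            seed=derive_seed(seed, "mix"),
        )
        if keep_clean_only:
            patches = remove_noisy(patches)
    model = UNet(cfg.model, seed=derive_seed(seed, "init"))
    train_cfg = TrainConfig(
        epochs=cfg.train.epochs,
        batch_size=cfg.train.batch_size,
        learning_rate=cfg.train.learning_rate,
        momentum=cfg.train.momentum,
        seed=derive_seed(seed, "train"),
    )
    train(model, patches, train_cfg)
    reports = [evaluate_sample(model, t, cfg, condition=spec) for t in test_samples]
    return model, reports, patches


def _rows(reports, sample_ids, extra: dict) -> list[dict]:
    rows = []
    for rep, sid in zip(reports, sample_ids):
        row = {"sample_id": sid, **extra, **rep.as_row()}
        rows.append(row)
    return rows


def preprocess_dataset(samples: Sequence[FundusSample], cfg: ExperimentConfig):
    return [preprocess(s, cfg.preprocess) for s in samples]


def sweep_noise_level(
    train_samples: Sequence[FundusSample],
    test_samples: Sequence[FundusSample],
    lam_list: Sequence[float],
    cfg: ExperimentConfig,
    seed: int = 0,
) -> pd.DataFrame:
    """Deform all training labels (ratio 1) at each level; evaluate on clean
    test labels. One CSV row per (level, sample)."""
    cfg = cfg.validate()
    rows: list[dict] = []
    base = prepare_patches(train_samples, cfg, derive_seed(seed, "patches"))
    for k, lam in enumerate(lam_list):
        spec = NoiseSpec(noise_level=lam, noise_ratio=1.0 if lam > 0 else 0.0,
                         corruption="nonlinear", direction_mode=cfg.direction_mode)
        _, reports, _ = run_condition(
            train_samples, test_samples, cfg, spec, derive_seed(seed, "cond", k), patches=base
        )
        rows += _rows(reports, [t.sample_id for t in test_samples], {"noise_level": lam})
        logger.info("noise level %.2f done", lam)
    return pd.DataFrame(rows)


def sweep_noise_ratio(
    train_samples: Sequence[FundusSample],
    test_samples: Sequence[FundusSample],
    lam_list: Sequence[float],
    rho_list: Sequence[float],
    cfg: ExperimentConfig,
    seed: int = 0,
) -> pd.DataFrame:
    """Cross the level grid with the clean/noisy mixing-ratio grid."""
    cfg = cfg.validate()
    rows: list[dict] = []
    base = prepare_patches(train_samples, cfg, derive_seed(seed, "patches"))
    for k, lam in enumerate(lam_list):
        for j, rho in enumerate(rho_list):
            spec = NoiseSpec(noise_level=lam, noise_ratio=rho,
                             corruption="nonlinear", direction_mode=cfg.direction_mode)
            _, reports, _ = run_condition(
                train_samples, test_samples, cfg, spec,
                derive_seed(seed, "cond", k, j), patches=base,
            )
            rows += _rows(
                reports,
                [t.sample_id for t in test_samples],
                {"noise_level": lam, "noise_ratio": rho},
            )
    return pd.DataFrame(rows)


def sweep_noise_type(
    train_samples: Sequence[FundusSample],
    test_samples: Sequence[FundusSample],
    kinds: Sequence[str],
    lam: float,
    cfg: ExperimentConfig,
    seed: int = 0,
) -> pd.DataFrame:
    """Compare the non-linear label deformation against image-level
    corruptions (each trained fresh at strength ``lam``)."""
    cfg = cfg.validate()
    rows: list[dict] = []
    for k, kind in enumerate(kinds):
        if kind == "none":
            spec = NoiseSpec(corruption="none")
        elif kind == "nonlinear":
            spec = NoiseSpec(noise_level=lam, noise_ratio=1.0, corruption="nonlinear",
                             direction_mode=cfg.direction_mode)
        else:
            spec = NoiseSpec(noise_level=lam, noise_ratio=0.0, corruption=kind)
        _, reports, _ = run_condition(
            train_samples, test_samples, cfg, spec, derive_seed(seed, "cond", k)
        )
        rows += _rows(
            reports, [t.sample_id for t in test_samples], {"corruption": kind, "noise_level": lam}
        )
    return pd.DataFrame(rows)


def cleaning_comparison(
    train_samples: Sequence[FundusSample],
    test_samples: Sequence[FundusSample],
    lam: float,
    rho_list: Sequence[float],
    cfg: ExperimentConfig,
    seed: int = 0,
) -> pd.DataFrame:
    """Paired arms per ratio: train on the full mixed pool ('noisy') vs on
    the clean subset after removing the deformed patches ('cleaned')."""
    cfg = cfg.validate()
    rows: list[dict] = []
    base = prepare_patches(train_samples, cfg, derive_seed(seed, "patches"))
    for k, rho in enumerate(rho_list):
        if not 0.0 < rho < 1.0:
            raise ValueError("cleaning comparison requires ratios strictly inside (0, 1)")
        spec = NoiseSpec(noise_level=lam, noise_ratio=rho, corruption="nonlinear",
                         direction_mode=cfg.direction_mode)
        for arm, clean_only in (("noisy", False), ("cleaned", True)):
            _, reports, used = run_condition(
                train_samples, test_samples, cfg, spec,
                derive_seed(seed, "cond", k), patches=base, keep_clean_only=clean_only,
            )
            rows += _rows(
                reports,
                [t.sample_id for t in test_samples],
                {"noise_level": lam, "noise_ratio": rho, "arm": arm, "n_patches": len(used)},
            )
    return pd.DataFrame(rows)


def summarize(table: pd.DataFrame, by: Sequence[str]) -> pd.DataFrame:
    """Per-condition means of the derived metrics."""
    cols = [c for c in ("acc", "sp", "sn", "precision", "f1", "auc") if c in table.columns]
    return table.groupby(list(by), dropna=False)[cols].mean().reset_index()
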