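"""Lightweight U-Net with dynamic-attention refinement.

Encoder stages apply two same-padded 3x3 convolutions (each with batch
normalization and ReLU) followed by dropout and a stride-2 max pool,
doubling the channel count per stage. The symmetric decoder upsamples by
2x2 nearest-neighbor, halves the channels, refines the matching skip
features with a dynamic attention block (scaled dot-product attention of
the pooled decoder state over the skip map's spatial positions), and
concatenates. A 1x1 convolution produces 2-channel logits; softmax gives
the per-pixel {background, vessel} probabilities trained with pixel-wise
cross entropy on one-hot labels.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from vesselnoise._nn import (
    AttentionBlock,
    BatchNorm2d,
    Conv2d,
    Dropout,
    Layer,
    MaxPool2,
    ReLU,
    Sequential,
    Upsample2,
    softmax,
)

ATTENTION_MODES = ("off", "bottleneck", "bottleneck_and_skips")


@dataclass
class ModelConfig:
    patch_size: int = 48
    depth: int = 4
    base_channels: int = 16
    dropout_rate: float = 0.2
    attention: str = "bottleneck_and_skips"
    classes: int = 2

    def validate(self) -> "ModelConfig":
        if self.attention not in ATTENTION_MODES:
            raise ValueError(f"unknown attention mode {self.attention!r}")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout rate must lie in [0, 1)")
        if self.classes != 2:
            raise ValueError("the segmenter is a two-class (vessel/background) model")
        if self.patch_size % (2**self.depth) != 0:
            raise ValueError(
                f"patch size {self.patch_size} is not divisible by 2^depth = {2 ** self.depth}"
            )
        return self


def dynamic_attention(H, d, W_Q, W_K, W_V, W_o):
    """One step of the dynamic attention mechanism (functional form).

    ``H`` is the (n, d_h) sequence of encoder hidden vectors and ``d`` the
    decoder state. Query/key/value projections give scores
    ``S = Q K^T / sqrt(d_k)``, normalized row-wise with softmax into
    weights ``A``; the context ``C = A V`` is concatenated with ``d`` and
    projected through ``W_o``. Returns ``(output, A)``.
    """
    H = np.atleast_2d(np.asarray(H, dtype=np.float64))
    d = np.asarray(d, dtype=np.float64)
    Q = W_Q @ d
    K = H @ np.asarray(W_K).T
    V = H @ np.asarray(W_V).T
    if K.shape[1] != Q.shape[0]:
        raise ValueError(f"query width {Q.shape[0]} does not match key width {K.shape[1]}")
    dk = Q.shape[0]
    S = K @ Q / np.sqrt(dk)
    S = S - S.max()
    A = np.exp(S)
    A = A / A.sum()
    C = A @ V
    z = np.concatenate([C, d])
    return np.asarray(W_o) @ z, A


def cross_entropy_loss(probs: np.ndarray, onehot: np.ndarray) -> float:
    """Pixel-wise cross entropy ``-(1/HW) sum y log p`` on one patch or batch.

    ``probs`` is (C, H, W) or (N, C, H, W) with channel probabilities
    summing to 1; ``onehot`` has the same shape with a valid one-hot
    encoding. Batches are averaged. Logs are clamped at 1e-12.
    """
    probs = np.asarray(probs, dtype=np.float64)
    onehot = np.asarray(onehot, dtype=np.float64)
    if probs.shape != onehot.shape:
        raise ValueError(f"probs shape {probs.shape} != labels shape {onehot.shape}")
    if probs.ndim == 3:
        probs, onehot = probs[None], onehot[None]
    if probs.ndim != 4:
        raise ValueError("expected (C, H, W) or (N, C, H, W) tensors")
    n, _, h, w = probs.shape
    return float(-np.sum(onehot * np.log(np.maximum(probs, 1e-12))) / (n * h * w))


class UNet:
    """The segmentation network; weights live in plain NumPy arrays."""

    def __init__(self, cfg: ModelConfig | None = None, seed: int = 0):
        self.cfg = (cfg or ModelConfig()).validate()
        cfg = self.cfg
        rng = np.random.default_rng(seed)
        self.rng = np.random.default_rng(seed + 1)  # dropout stream
        ch = [cfg.base_channels * 2**i for i in range(cfg.depth + 1)]

        def conv_block(cin, cout):
            return Sequential(
                [
                    Conv2d(cin, cout, 3, rng),
                    BatchNorm2d(cout),
                    ReLU(),
                    Conv2d(cout, cout, 3, rng),
                    BatchNorm2d(cout),
                    ReLU(),
                    Dropout(cfg.dropout_rate, self.rng),
                ]
            )

        self.enc_blocks = [conv_block(1 if i == 0 else ch[i - 1], ch[i]) for i in range(cfg.depth)]
        self.pools = [MaxPool2() for _ in range(cfg.depth)]
        self.bottleneck = conv_block(ch[cfg.depth - 1], ch[cfg.depth])
        self.att_bottleneck = (
            AttentionBlock(ch[cfg.depth], rng) if cfg.attention != "off" else None
        )
        self.ups = [Upsample2() for _ in range(cfg.depth)]
        self.up_convs = [
            Sequential([Conv2d(ch[i + 1], ch[i], 3, rng), BatchNorm2d(ch[i]), ReLU()])
            for i in range(cfg.depth)
        ]
        self.att_skips = [
            AttentionBlock(ch[i], rng) if cfg.attention == "bottleneck_and_skips" else None
            for i in range(cfg.depth)
        ]
        self.dec_blocks = [conv_block(2 * ch[i], ch[i]) for i in range(cfg.depth)]
        self.head = Conv2d(ch[0], cfg.classes, 1, rng)

    # -- structural helpers -------------------------------------------------
    def _modules(self):
        mods: list = []
        for blk in self.enc_blocks:
            mods.extend(blk.layers)
        mods.extend(self.bottleneck.layers)
        if self.att_bottleneck is not None:
            mods.append(self.att_bottleneck)
        for i in range(self.cfg.depth):
            mods.extend(self.up_convs[i].layers)
            if self.att_skips[i] is not None:
                mods.append(self.att_skips[i])
            mods.extend(self.dec_blocks[i].layers)
        mods.append(self.head)
        return mods

    def param_layers(self) -> list[Layer]:
        return [m for m in self._modules() if m.PARAMS]

    def param_count(self) -> int:
        return sum(m.param_count() for m in self.param_layers())

    def reseed_dropout(self, seed: int) -> None:
        rng = np.random.default_rng(seed)
        self.rng = rng
        for m in self._modules():
            if isinstance(m, Dropout):
                m.rng = rng

    # -- forward / backward --------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Logits (N, 2, s, s) for an input batch (N, 1, s, s)."""
        cfg = self.cfg
        skips = []
        for i in range(cfg.depth):
            x = self.enc_blocks[i].forward(x, train)
            skips.append(x)
            x = self.pools[i].forward(x, train)
        x = self.bottleneck.forward(x, train)
        if self.att_bottleneck is not None:
            ref = self.att_bottleneck.forward_pair(x, x, train)
            x = x + ref[:, :, None, None]
        self._skips = skips if train else None
        for i in reversed(range(cfg.depth)):
            x = self.ups[i].forward(x, train)
            x = self.up_convs[i].forward(x, train)
            skip = skips[i]
            if self.att_skips[i] is not None:
                ref = self.att_skips[i].forward_pair(skip, x, train)
                skip = skip + ref[:, :, None, None]
            if train:
                skips[i] = skip  # store the refined version for backward bookkeeping
            x = self.dec_blocks[i].forward(np.concatenate([skip, x], axis=1), train)
        return self.head.forward(x, train)

    def backward(self, dlogits: np.ndarray) -> None:
        cfg = self.cfg
        d = self.head.backward(dlogits)
        dskip_accum: list[np.ndarray | None] = [None] * cfg.depth
        for i in range(cfg.depth):
            dcat = self.dec_blocks[i].backward(d)
            c = dcat.shape[1] // 2
            dskip, d = dcat[:, :c], dcat[:, c:]
            if self.att_skips[i] is not None:
                denc, ddec = self.att_skips[i].backward_pair(dskip.sum(axis=(2, 3)))
                dskip = dskip + denc
                d = d + ddec
            dskip_accum[i] = dskip
            d = self.up_convs[i].backward(d)
            d = self.ups[i].backward(d)
        if self.att_bottleneck is not None:
            denc, ddec = self.att_bottleneck.backward_pair(d.sum(axis=(2, 3)))
            d = d + denc + ddec
        d = self.bottleneck.backward(d)
        for i in reversed(range(cfg.depth)):
            d = self.pools[i].backward(d)
            d = d + dskip_accum[i]
            d = self.enc_blocks[i].backward(d)
        self._skips = None

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Softmax class probabilities (N, 2, s, s) in inference mode."""
        return softmax(self.forward(x.astype(np.float32), train=False), axis=1)

    # -- persistence ----------------------------------------------------------
    def state_arrays(self) -> dict[str, np.ndarray]:
        state = {}
        for idx, m in enumerate(self._modules()):
            for name in getattr(m, "PARAMS", ()):
                state[f"p{idx}:{name}"] = getattr(m, name)
            if isinstance(m, BatchNorm2d):
                state[f"p{idx}:running_mean"] = m.running_mean
                state[f"p{idx}:running_var"] = m.running_var
        return state

    def save(self, path) -> None:
        np.savez(Path(path), __config__=json.dumps(asdict(self.cfg)), **self.state_arrays())

    @classmethod
    def load(cls, path) -> "UNet":
        with np.load(Path(path), allow_pickle=False) as data:
            cfg = ModelConfig(**json.loads(str(data["__config__"])))
            model = cls(cfg)
            for idx, m in enumerate(model._modules()):
                for name in getattr(m, "PARAMS", ()):
                    setattr(m, name, data[f"p{idx}:{name}"].copy())
                if isinstance(m, BatchNorm2d):
                    m.running_mean = data[f"p{idx}:running_mean"].copy()
                    m.running_var = data[f"p{idx}:running_var"].copy()
        return model


def build_model(cfg: ModelConfig | None = None, seed: int = 0):
    """Construct the network; returns ``(model, trainable_parameter_count)``."""
    model = UNet(cfg, seed=seed)
    return model, model.param_count()


def predict_patches(model: UNet, patches: np.ndarray, batch_size: int = 128) -> np.ndarray:
    """Vessel-probability rasters (N, s, s) for a stack of image patches.

    8-bit inputs are scaled onto [0, 1]; the class-1 (vessel) channel of
    the softmax output is returned.
    """
    patches = np.asarray(patches)
    if patches.ndim != 3 or patches.shape[1] != patches.shape[2]:
        raise ValueError(f"expected (N, s, s) square patches, got {patches.shape}")
    if patches.shape[1] != model.cfg.patch_size:
        raise ValueError(
            f"patch size {patches.shape[1]} does not match model input {model.cfg.patch_size}"
        )
    x = patches.astype(np.float32)
    if patches.dtype == np.uint8:
        x = x / 255.0
    out = np.empty((len(x), patches.shape[1], patches.shape[2]), dtype=np.float64)
    for start in range(0, len(x), batch_size):
        chunk = x[start : start + batch_size, None]
        out[start : start + batch_size] = model.predict_proba(chunk)[:, 1]
    return out
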