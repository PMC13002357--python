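"""Minimal NumPy layers with hand-written backpropagation.

Only what the lightweight U-Net needs: same-padded convolutions (sums of
shifted channels-last GEMMs), batch normalization, ReLU, dropout, 2x2 max
pooling, 2x2 nearest-neighbor upsampling, and SGD with momentum. Tensors
are (N, C, H, W) float32. Each layer caches what its backward pass needs
during ``forward(..., train=True)`` and stores parameter gradients on
itself (``dW`` for ``W`` etc.) during ``backward``.
"""

from __future__ import annotations

import numpy as np


class Layer:
    PARAMS: tuple[str, ...] = ()

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def param_count(self) -> int:
        return sum(getattr(self, name).size for name in self.PARAMS)


class Conv2d(Layer):
    """k x k convolution with zero padding preserving H and W (stride 1).

    Computed as a sum of k*k shifted channels-last GEMMs, which keeps every
    matrix product contiguous and BLAS-friendly.
    """

    PARAMS = ("W", "b")

    def __init__(self, cin: int, cout: int, ksize: int, rng: np.random.Generator):
        std = np.sqrt(2.0 / (cin * ksize * ksize))
        self.W = rng.normal(0.0, std, size=(cout, cin, ksize, ksize)).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.ksize = ksize
        self.pad = ksize // 2

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        k, p = self.ksize, self.pad
        n, _, h, w = x.shape
        xt = x.transpose(0, 2, 3, 1)  # NHWC
        xp = np.pad(xt, ((0, 0), (p, p), (p, p), (0, 0))) if p else np.ascontiguousarray(xt)
        wm = self.W.transpose(2, 3, 1, 0)  # (k, k, Cin, Cout)
        out = np.zeros((n, h, w, self.W.shape[0]), dtype=xp.dtype)
        for i in range(k):
            for j in range(k):
                out += xp[:, i : i + h, j : j + w, :] @ wm[i, j]
        out += self.b
        if train:
            self._xp = xp
            self._shape = x.shape
        return out.transpose(0, 3, 1, 2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, _, h, w = self._shape
        k, p = self.ksize, self.pad
        xp = self._xp
        dt = np.ascontiguousarray(dout.transpose(0, 2, 3, 1))  # NHWO
        wm = self.W.transpose(2, 3, 1, 0)
        dwm = np.empty_like(wm)
        dxp = np.zeros_like(xp)
        for i in range(k):
            for j in range(k):
                s = xp[:, i : i + h, j : j + w, :]
                dwm[i, j] = np.tensordot(s, dt, axes=([0, 1, 2], [0, 1, 2]))
                dxp[:, i : i + h, j : j + w, :] += dt @ wm[i, j].T
        self.dW = dwm.transpose(3, 2, 0, 1)
        self.db = dt.sum(axis=(0, 1, 2))
        self._xp = None
        dx = dxp[:, p : p + h, p : p + w, :] if p else dxp
        return dx.transpose(0, 3, 1, 2)


class BatchNorm2d(Layer):
    PARAMS = ("gamma", "beta")

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(channels, dtype=np.float32)
        self.beta = np.zeros(channels, dtype=np.float32)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (
                self.momentum * self.running_mean + (1 - self.momentum) * mean
            ).astype(np.float32)
            self.running_var = (
                self.momentum * self.running_var + (1 - self.momentum) * var
            ).astype(np.float32)
            invstd = 1.0 / np.sqrt(var + self.eps)
            xhat = (x - mean[None, :, None, None]) * invstd[None, :, None, None]
            self._xhat = xhat
            self._invstd = invstd
        else:
            invstd = 1.0 / np.sqrt(self.running_var + self.eps)
            xhat = (x - self.running_mean[None, :, None, None]) * invstd[None, :, None, None]
        return self.gamma[None, :, None, None] * xhat + self.beta[None, :, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, invstd = self._xhat, self._invstd
        m = dout.shape[0] * dout.shape[2] * dout.shape[3]
        self.dgamma = (dout * xhat).sum(axis=(0, 2, 3))
        self.dbeta = dout.sum(axis=(0, 2, 3))
        dxhat = dout * self.gamma[None, :, None, None]
        t1 = dxhat.sum(axis=(0, 2, 3), keepdims=True)
        t2 = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
        dx = (invstd[None, :, None, None] / m) * (m * dxhat - t1 - xhat * t2)
        self._xhat = None
        return dx


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class Dropout(Layer):
    """Inverted dropout; active only in training. ``rng`` is shared with the
    owning model so one reseed fixes the whole stochastic forward pass."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self.rate == 0.0:
            return dout
        return dout * self._mask


class MaxPool2(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xr = xr.reshape(n, c, h // 2, w // 2, 4)
        if train:
            self._argmax = xr.argmax(axis=-1)
            self._inshape = x.shape
        return xr.max(axis=-1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._inshape
        dxr = np.zeros((n, c, h // 2, w // 2, 4), dtype=dout.dtype)
        np.put_along_axis(dxr, self._argmax[..., None], dout[..., None], axis=-1)
        dx = dxr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return dx.reshape(n, c, h, w)


class Upsample2(Layer):
    """Parameter-free 2x2 nearest-neighbor upsampling."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h2, w2 = dout.shape
        return dout.reshape(n, c, h2 // 2, 2, w2 // 2, 2).sum(axis=(3, 5))


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def param_layers(self) -> list[Layer]:
        return [l for l in self.layers if l.PARAMS]

    def param_count(self) -> int:
        return sum(l.param_count() for l in self.layers)


class AttentionBlock(Layer):
    """Scaled dot-product attention over the spatial positions of a map.

    The spatial positions of the encoder feature map form the key/value
    sequence; the decoder map, mean-pooled to a vector, is the query state.
    The context vector is concatenated with the decoder state and projected
    back to the channel width; the caller broadcast-adds the result to the
    features being refined.
    """

    PARAMS = ("Wq", "Wk", "Wv", "Wo")

    def __init__(self, channels: int, rng: np.random.Generator):
        c = channels
        std = 1.0 / np.sqrt(c)
        self.Wq = rng.normal(0.0, std, size=(c, c)).astype(np.float32)
        self.Wk = rng.normal(0.0, std, size=(c, c)).astype(np.float32)
        self.Wv = rng.normal(0.0, std, size=(c, c)).astype(np.float32)
        self.Wo = rng.normal(0.0, std, size=(c, 2 * c)).astype(np.float32)
        self.channels = c

    def forward_pair(self, enc: np.ndarray, dec: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = enc.shape
        hseq = enc.reshape(n, c, h * w).transpose(0, 2, 1)  # (N, n_pos, C)
        dvec = dec.mean(axis=(2, 3))  # (N, C)
        q = dvec @ self.Wq.T
        k = hseq @ self.Wk.T
        v = hseq @ self.Wv.T
        scores = np.einsum("nk,nmk->nm", q, k) / np.sqrt(c)
        scores -= scores.max(axis=1, keepdims=True)
        a = np.exp(scores)
        a /= a.sum(axis=1, keepdims=True)
        ctx = np.einsum("nm,nmv->nv", a, v)
        z = np.concatenate([ctx, dvec], axis=1)
        if train:
            self._cache = (hseq, dvec, q, k, v, a, z, (n, c, h, w))
        return z @ self.Wo.T

    def backward_pair(self, dout: np.ndarray):
        hseq, dvec, q, k, v, a, z, (n, c, h, w) = self._cache
        self.dWo = dout.T @ z
        dz = dout @ self.Wo
        dctx, ddvec = dz[:, :c], dz[:, c:].copy()
        da = np.einsum("nv,nmv->nm", dctx, v)
        dv = a[:, :, None] * dctx[:, None, :]
        ds = a * (da - (a * da).sum(axis=1, keepdims=True))
        dq = np.einsum("nm,nmk->nk", ds, k) / np.sqrt(c)
        dk = ds[:, :, None] * q[:, None, :] / np.sqrt(c)
        ddvec += dq @ self.Wq
        self.dWq = dq.T @ dvec
        dh = dk @ self.Wk + dv @ self.Wv
        self.dWk = np.einsum("nmk,nmc->kc", dk, hseq)
        self.dWv = np.einsum("nmv,nmc->vc", dv, hseq)
        denc = dh.transpose(0, 2, 1).reshape(n, c, h, w)
        ddec = np.broadcast_to((ddvec / (h * w))[:, :, None, None], (n, c, h, w)).copy()
        self._cache = None
        return denc, ddec


class SGD:
    """Stochastic gradient descent with classical momentum."""

    def __init__(self, lr: float = 0.1, momentum: float = 0.9):
        self.lr = lr
        self.momentum = momentum
        self._velocity: dict[tuple[int, str], np.ndarray] = {}

    def step(self, layers: list[Layer]) -> None:
        for idx, layer in enumerate(layers):
            for name in layer.PARAMS:
                p = getattr(layer, name)
                g = getattr(layer, "d" + name)
                key = (idx, name)
                v = self._velocity.get(key)
                if v is None:
                    v = np.zeros_like(p)
                v = self.momentum * v - self.lr * g.astype(p.dtype)
                self._velocity[key] = v
                p += v


def softmax(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    shifted = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, onehot: np.ndarray):
    """Mean pixel-wise cross entropy over a batch and its logits gradient."""
    probs = softmax(logits, axis=1)
    n = logits.shape[0]
    hw = logits.shape[2] * logits.shape[3]
    loss = -np.sum(onehot * np.log(np.maximum(probs, 1e-12))) / (n * hw)
    dlogits = (probs - onehot) / (n * hw)
    return float(loss), dlogits
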