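"""Minimal numpy CNN building blocks with explicit backward passes.

Single-image (H, W, C) layout throughout.  Convolutions are im2col matrix
products; backward passes accumulate parameter gradients in-place and
return the input gradient.  An SGD-with-momentum optimizer updates all
registered parameters.  Everything is deterministic given the seed used to
initialize the layers (up to floating-point reduction order).
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv2D", "Dropout", "SGDMomentum", "im2col"]


def im2col(x: np.ndarray, k: int, stride: int, pad: int) -> tuple[np.ndarray, tuple]:
    """Unfold an (H, W, C) array into (Ho*Wo, k*k*C) patch rows."""
    if pad:
        x = np.pad(x, ((pad, pad), (pad, pad), (0, 0)))
    H, W, C = x.shape
    Ho = (H - k) // stride + 1
    Wo = (W - k) // stride + 1
    s0, s1, s2 = x.strides
    view = np.lib.stride_tricks.as_strided(
        x, (Ho, Wo, k, k, C), (s0 * stride, s1 * stride, s0, s1, s2)
    )
    return view.reshape(Ho * Wo, k * k * C), (H, W, C, Ho, Wo)


def _col2im(dcols: np.ndarray, meta: tuple, k: int, stride: int, pad: int) -> np.ndarray:
    H, W, C, Ho, Wo = meta
    dx = np.zeros((H, W, C), dtype=dcols.dtype)
    dcols = dcols.reshape(Ho, Wo, k, k, C)
    for i in range(k):
        for j in range(k):
            dx[i : i + Ho * stride : stride, j : j + Wo * stride : stride] += dcols[:, :, i, j]
    if pad:
        dx = dx[pad:-pad, pad:-pad]
    return dx


class Conv2D:
    """2-D convolution (optionally followed by ReLU) with backprop.

    He-normal initialization from the supplied generator.
    """

    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        ksize: int = 3,
        stride: int = 1,
        pad: int = 1,
        relu: bool = True,
        rng: np.random.Generator | None = None,
    ) -> None:
        self.ksize, self.stride, self.pad, self.relu = ksize, stride, pad, relu
        self.in_ch, self.out_ch = in_ch, out_ch
        self.lr_mult = 1.0  # per-layer learning-rate multiplier
        rng = rng or np.random.default_rng(0)
        fan_in = ksize * ksize * in_ch
        # float32 throughout: halves the cost of the im2col products
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                            size=(out_ch, fan_in)).astype(np.float32)
        self.b = np.zeros(out_ch, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        cols, meta = im2col(x, self.ksize, self.stride, self.pad)
        out = cols @ self.W.T + self.b
        Ho, Wo = meta[3], meta[4]
        out = out.reshape(Ho, Wo, self.out_ch)
        mask = None
        if self.relu:
            mask = out > 0
            out = out * mask
        if train:
            self._cache = (cols, meta, mask)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, meta, mask = self._cache
        dout = dout.astype(np.float32, copy=False)
        if self.relu:
            dout = dout * mask
        d2 = dout.reshape(-1, self.out_ch)
        self.dW += d2.T @ cols
        self.db += d2.sum(axis=0)
        dcols = d2 @ self.W
        return _col2im(dcols, meta, self.ksize, self.stride, self.pad)

    def params(self):
        return [(self.W, self.dW, self.lr_mult), (self.b, self.db, self.lr_mult)]

    def zero_grad(self) -> None:
        self.dW[...] = 0.0
        self.db[...] = 0.0


class Dropout:
    """Inverted dropout; identity at inference time."""

    def __init__(self, rate: float) -> None:
        if not (0.0 <= rate < 1.0):
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate
        self._mask = None

    def forward(self, x: np.ndarray, rng: np.random.Generator, train: bool) -> np.ndarray:
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = ((rng.random(x.shape) < keep) / keep).astype(np.float32)
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout if self._mask is None else dout * self._mask


class SGDMomentum:
    """Classical momentum SGD over (param, grad, lr_mult) triples."""

    def __init__(self, params: list, lr: float, momentum: float, clip_norm: float = 10.0):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self.clip_norm = clip_norm
        self.velocity = [np.zeros_like(p) for p, _, _ in params]

    def step(self) -> None:
        if self.clip_norm is not None:
            total = np.sqrt(sum(float((g * g).sum()) for _, g, _ in self.params))
            if total > self.clip_norm:
                scale = self.clip_norm / (total + 1e-12)
                for _, g, _ in self.params:
                    g *= scale
        for v, (p, g, mult) in zip(self.velocity, self.params):
            v *= self.momentum
            v -= self.lr * mult * g
            p += v

    def zero_grad(self) -> None:
        for _, g, _ in self.params:
            g[...] = 0.0


# -- stable primitives -------------------------------------------------------

def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def bce_with_logits(logits: np.ndarray, targets: np.ndarray) -> np.ndarray:
    """Elementwise binary cross-entropy on logits (numerically stable)."""
    return np.maximum(logits, 0.0) - logits * targets + np.log1p(np.exp(-np.abs(logits)))


def smooth_l1(x: np.ndarray) -> np.ndarray:
    ax = np.abs(x)
    return np.where(ax < 1.0, 0.5 * x * x, ax - 0.5)


def smooth_l1_grad(x: np.ndarray) -> np.ndarray:
    return np.clip(x, -1.0, 1.0)
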