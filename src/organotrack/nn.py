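"""Minimal trainable convolutional-network engine in pure NumPy.

Implements exactly the primitives a compact u-net needs — 3x3 "same"
convolutions, 2x2 max-pooling, 2x2-stride-2 transposed convolutions, channel
concatenation, ELU/sigmoid activations, inverted dropout, binary cross-entropy
on logits, He initialisation and the Adam optimiser — with hand-written
backward passes.  Data layout is NHWC, float32 throughout.

The engine is deliberately small: layers cache what their backward pass needs
on ``forward`` and release it on ``backward``; parameters are plain arrays
exposed through ``params()`` so the optimiser and checkpointing can treat a
network as a flat list.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

F32 = np.float32


class Layer:
    """Base class: a differentiable op with optional trainable parameters."""

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2D(Layer):
    """k x k convolution, stride 1, 'same' zero padding, with bias.

    Forward runs as an im2col matmul; backward folds the column gradient back
    with a k*k-step accumulation loop (cheap for k=3).
    """

    def __init__(self, in_ch: int, out_ch: int, k: int = 3, rng: np.random.Generator | None = None):
        self.in_ch, self.out_ch, self.k = in_ch, out_ch, k
        rng = rng or np.random.default_rng()
        fan_in = k * k * in_ch
        # He normal: appropriate for the ELU/ReLU family
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(k, k, in_ch, out_ch)).astype(F32)
        self.b = np.zeros(out_ch, dtype=F32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def forward(self, x, train):
        k = self.k
        p = k // 2
        n, h, w, c = x.shape
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        cols = sliding_window_view(xp, (k, k), axis=(1, 2))  # (n,h,w,c,k,k)
        cols = cols.transpose(0, 1, 2, 4, 5, 3).reshape(n * h * w, k * k * c)
        self._cols = cols
        self._xshape = x.shape
        y = cols @ self.W.reshape(k * k * c, self.out_ch) + self.b
        return y.reshape(n, h, w, self.out_ch)

    def backward(self, dy):
        k, p = self.k, self.k // 2
        n, h, w, c = self._xshape
        dyf = dy.reshape(n * h * w, self.out_ch)
        self.dW[...] = (self._cols.T @ dyf).reshape(self.W.shape)
        self.db[...] = dyf.sum(axis=0)
        dcols = (dyf @ self.W.reshape(k * k * c, self.out_ch).T).reshape(n, h, w, k, k, c)
        dxp = np.zeros((n, h + 2 * p, w + 2 * p, c), dtype=F32)
        for i in range(k):
            for j in range(k):
                dxp[:, i:i + h, j:j + w, :] += dcols[:, :, :, i, j, :]
        self._cols = None
        return dxp[:, p:p + h, p:p + w, :]


class ConvTranspose2D(Layer):
    """2x2 transposed convolution with stride 2 (standard u-net up-sampling)."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator | None = None):
        self.in_ch, self.out_ch = in_ch, out_ch
        rng = rng or np.random.default_rng()
        fan_in = 4 * in_ch
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(2, 2, in_ch, out_ch)).astype(F32)
        self.b = np.zeros(out_ch, dtype=F32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def forward(self, x, train):
        # y[n, 2h+i, 2w+j, f] = sum_c x[n,h,w,c] W[i,j,c,f]
        self._x = x
        n, h, w, c = x.shape
        y6 = np.einsum("nhwc,ijcf->nhiwjf", x, self.W, optimize=True)
        return y6.reshape(n, 2 * h, 2 * w, self.out_ch) + self.b

    def backward(self, dy):
        x = self._x
        n, h, w, c = x.shape
        dy6 = dy.reshape(n, h, 2, w, 2, self.out_ch)
        self.dW[...] = np.einsum("nhwc,nhiwjf->ijcf", x, dy6, optimize=True)
        self.db[...] = dy.sum(axis=(0, 1, 2))
        dx = np.einsum("nhiwjf,ijcf->nhwc", dy6, self.W, optimize=True)
        self._x = None
        return dx


class MaxPool2x2(Layer):
    def forward(self, x, train):
        n, h, w, c = x.shape
        r = x.reshape(n, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 5, 2, 4)
        r = r.reshape(n, h // 2, w // 2, c, 4)
        self._idx = r.argmax(axis=-1)
        self._shape = x.shape
        return np.take_along_axis(r, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dy):
        n, h, w, c = self._shape
        g = np.zeros((n, h // 2, w // 2, c, 4), dtype=F32)
        np.put_along_axis(g, self._idx[..., None], dy[..., None], axis=-1)
        g = g.reshape(n, h // 2, w // 2, c, 2, 2).transpose(0, 1, 4, 2, 5, 3)
        self._idx = None
        return g.reshape(n, h, w, c)


class ELU(Layer):
    def __init__(self, alpha: float = 1.0):
        self.alpha = alpha

    def forward(self, x, train):
        y = np.where(x > 0, x, self.alpha * np.expm1(np.minimum(x, 0.0)))
        self._x_pos = x > 0
        self._y = y
        return y

    def backward(self, dy):
        dx = dy * np.where(self._x_pos, 1.0, self._y + self.alpha)
        self._x_pos = self._y = None
        return dx


class ReLU(Layer):
    def forward(self, x, train):
        self._pos = x > 0
        return np.where(self._pos, x, 0.0)

    def backward(self, dy):
        dx = np.where(self._pos, dy, 0.0)
        self._pos = None
        return dx


class Dropout(Layer):
    """Inverted dropout: active only when train=True, identity otherwise."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x, train):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(F32) / keep
        return x * self._mask

    def backward(self, dy):
        if self._mask is None:
            return dy
        dx = dy * self._mask
        self._mask = None
        return dx


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(z: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy computed stably from logits.

    Returns (loss, dloss/dz).  Target is {0,1}-valued, same shape as z.
    """
    z = z.astype(np.float64)
    loss = np.mean(np.maximum(z, 0) - z * target + np.log1p(np.exp(-np.abs(z))))
    dz = (sigmoid(z) - target) / z.size
    return float(loss), dz.astype(F32)


class Adam:
    """Adam optimiser over a flat list of parameter arrays (in-place updates)."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * (g * g)
            p -= (self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)).astype(p.dtype)
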