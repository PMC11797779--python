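"""Minimal NumPy neural-network engine for the U-Net segmenter.

Implements exactly the layers a classic U-Net needs — 3x3 same-padding
convolution, ReLU, 2x2 max-pool, 2x2 stride-2 transposed convolution,
channel concatenation, 1x1 convolution — with hand-written backward passes
(im2col/col2im for the 3x3 convolutions) and an Adam optimizer.  Data
layout is NCHW, float32.

This is a training engine for desk-scale models; it favours clarity and
exact reproducibility (single-threaded NumPy, seeded init) over speed.
"""

from __future__ import annotations

from typing import List, Optional, Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Layer", "Conv3x3", "BatchNorm2d", "ReLU", "MaxPool2", "UpConv2x2",
    "Conv1x1", "Adam", "sigmoid",
]


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class Layer:
    """Base layer: forward caches what backward needs."""

    def params(self) -> List[np.ndarray]:
        return []

    def grads(self) -> List[np.ndarray]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv3x3(Layer):
    """3x3 convolution, stride 1, same (zero) padding."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        std = np.sqrt(2.0 / (c_in * 9))  # He init for ReLU nets
        self.w = rng.normal(0.0, std, size=(c_out, c_in, 3, 3)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._x_col: Optional[np.ndarray] = None
        self._x_shape: Optional[Tuple[int, ...]] = None

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.dw, self.db]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        win = sliding_window_view(xp, (3, 3), axis=(2, 3))  # (n, c, h, w, 3, 3)
        x_col = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * 9)
        self._x_col = np.ascontiguousarray(x_col, dtype=np.float32)
        self._x_shape = x.shape
        w_mat = self.w.reshape(self.w.shape[0], -1)
        y = self._x_col @ w_mat.T + self.b
        return y.reshape(n, h, w, -1).transpose(0, 3, 1, 2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c_out, h, w = dy.shape
        _, c_in, _, _ = self._x_shape
        dy_mat = dy.transpose(0, 2, 3, 1).reshape(n * h * w, c_out)
        self.dw[...] = (dy_mat.T @ self._x_col).reshape(self.w.shape)
        self.db[...] = dy_mat.sum(axis=0)
        dx_col = dy_mat @ self.w.reshape(c_out, -1)  # (n*h*w, c_in*9)
        dx_col = dx_col.reshape(n, h, w, c_in, 3, 3).transpose(0, 3, 4, 5, 1, 2)
        dxp = np.zeros((n, c_in, h + 2, w + 2), dtype=np.float32)
        for ki in range(3):
            for kj in range(3):
                dxp[:, :, ki : ki + h, kj : kj + w] += dx_col[:, :, ki, kj]
        self._x_col = None
        return dxp[:, :, 1:-1, 1:-1]


class BatchNorm2d(Layer):
    """Per-channel batch normalization with running statistics.

    Uses batch statistics when ``self.training`` is True and the running
    (exponential moving average) statistics otherwise.
    """

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(channels, dtype=np.float32)
        self.beta = np.zeros(channels, dtype=np.float32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps
        self.training = True

    def params(self):
        return [self.gamma, self.beta]

    def grads(self):
        return [self.dgamma, self.dbeta]

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean *= self.momentum
            self.running_mean += (1 - self.momentum) * mean
            self.running_var *= self.momentum
            self.running_var += (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        x_hat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
        if self.training:
            self._x_hat = x_hat.astype(np.float32)
            self._inv_std = inv_std.astype(np.float32)
        y = self.gamma[None, :, None, None] * x_hat + self.beta[None, :, None, None]
        return y.astype(np.float32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x_hat = self._x_hat
        self.dgamma[...] = (dy * x_hat).sum(axis=(0, 2, 3))
        self.dbeta[...] = dy.sum(axis=(0, 2, 3))
        g = self.gamma[None, :, None, None] * self._inv_std[None, :, None, None]
        mean_dy = dy.mean(axis=(0, 2, 3))[None, :, None, None]
        mean_dy_xhat = (dy * x_hat).mean(axis=(0, 2, 3))[None, :, None, None]
        dx = g * (dy - mean_dy - x_hat * mean_dy_xhat)
        self._x_hat = None
        return dx.astype(np.float32)


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(np.float32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, 0.0).astype(np.float32)


class MaxPool2(Layer):
    """2x2 max-pooling, stride 2; gradient routed to the first argmax."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError("MaxPool2 requires even spatial dimensions")
        blocks = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        flat = blocks.reshape(n, c, h // 2, w // 2, 4)
        self._argmax = flat.argmax(axis=-1)
        self._in_shape = x.shape
        return np.take_along_axis(flat, self._argmax[..., None], axis=-1)[..., 0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._in_shape
        flat = np.zeros((n, c, h // 2, w // 2, 4), dtype=np.float32)
        np.put_along_axis(flat, self._argmax[..., None], dy[..., None], axis=-1)
        blocks = flat.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return blocks.reshape(n, c, h, w)


class UpConv2x2(Layer):
    """Transposed 2x2 convolution with stride 2 (learned 2x upsampling)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        std = np.sqrt(2.0 / (c_in * 4))
        self.w = rng.normal(0.0, std, size=(c_in, c_out, 2, 2)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.dw, self.db]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        n, c, h, w = x.shape
        y = np.einsum("nchw,cokl->nohkwl", x, self.w, optimize=True)
        y = y.reshape(n, self.w.shape[1], 2 * h, 2 * w)
        return (y + self.b[None, :, None, None]).astype(np.float32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c_out, h2, w2 = dy.shape
        blocks = dy.reshape(n, c_out, h2 // 2, 2, w2 // 2, 2)  # n,o,h,k,w,l
        self.dw[...] = np.einsum("nchw,nohkwl->cokl", self._x, blocks, optimize=True)
        self.db[...] = dy.sum(axis=(0, 2, 3))
        dx = np.einsum("nohkwl,cokl->nchw", blocks, self.w, optimize=True)
        self._x = None
        return dx.astype(np.float32)


class Conv1x1(Layer):
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        std = np.sqrt(2.0 / c_in)
        self.w = rng.normal(0.0, std, size=(c_out, c_in)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.dw, self.db]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        y = np.einsum("nchw,oc->nohw", x, self.w, optimize=True)
        return (y + self.b[None, :, None, None]).astype(np.float32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.dw[...] = np.einsum("nohw,nchw->oc", dy, self._x, optimize=True)
        self.db[...] = dy.sum(axis=(0, 2, 3))
        dx = np.einsum("nohw,oc->nchw", dy, self.w, optimize=True)
        self._x = None
        return dx.astype(np.float32)


class Adam:
    """Adam optimizer over a flat list of parameter arrays."""

    def __init__(self, params: List[np.ndarray], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: List[np.ndarray]) -> None:
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * (g * g)
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
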