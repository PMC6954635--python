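"""Minimal NumPy neural-network layers used by the multimodal autoencoder.

Implements exactly what the fused-embedding model needs — 2-D 'same'
convolutions with stride (im2col + matmul), nearest-neighbour upsampling,
dense layers, ReLU, and the ADAM optimizer — with reverse-mode gradients
written by hand.  Layers are float32 by default (float64 available for
verification) and driven by explicit ``numpy.random.Generator`` instances,
so runs are bit-reproducible and batched evaluation matches per-item
evaluation to rounding error.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Conv2d", "Upsample2x", "Crop2d", "Dense", "Adam", "Layer"]


class Layer:
    """Base class: ``forward(x)`` caches, ``backward(dy)`` returns dx."""

    def parameters(self) -> list[np.ndarray]:
        return []

    def gradients(self) -> list[np.ndarray]:
        return []


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


class Conv2d(Layer):
    """3x3-style convolution, 'same' padding, integer stride, optional ReLU.

    Output spatial size is ``ceil(in / stride)``.  He-normal weight
    initialization.
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int = 3,
        stride: int = 1,
        relu: bool = True,
        rng: np.random.Generator | None = None,
        dtype=np.float32,
    ):
        rng = rng or np.random.default_rng()
        k = kernel_size
        fan_in = in_channels * k * k
        self.dtype = np.dtype(dtype)
        self.w = (rng.standard_normal((out_channels, in_channels, k, k)) * np.sqrt(2.0 / fan_in)).astype(self.dtype)
        self.b = np.zeros(out_channels, dtype=self.dtype)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self.stride = stride
        self.k = k
        self.relu = relu
        self._cols: np.ndarray | None = None
        self._y: np.ndarray | None = None

    def parameters(self):
        return [self.w, self.b]

    def gradients(self):
        return [self.dw, self.db]

    def _geometry(self, h: int, w: int):
        s, k = self.stride, self.k
        oh = -(-h // s)
        ow = -(-w // s)
        pad_h = max((oh - 1) * s + k - h, 0)
        pad_w = max((ow - 1) * s + k - w, 0)
        return oh, ow, (pad_h // 2, pad_h - pad_h // 2), (pad_w // 2, pad_w - pad_w // 2)

    def _im2col(self, x: np.ndarray):
        b, c, h, w = x.shape
        oh, ow, ph, pw = self._geometry(h, w)
        xp = np.pad(x, ((0, 0), (0, 0), ph, pw))
        win = sliding_window_view(xp, (self.k, self.k), axis=(2, 3))
        win = win[:, :, :: self.stride, :: self.stride][:, :, :oh, :ow]
        # (B, OH, OW, C*k*k)
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(b, oh, ow, c * self.k * self.k)
        return cols, (oh, ow, ph, pw, xp.shape)

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=self.dtype)
        self._in_shape = x.shape
        cols, geom = self._im2col(x)
        self._cols, self._geom = cols, geom
        oh, ow = geom[0], geom[1]
        b = x.shape[0]
        w2 = self.w.reshape(self.w.shape[0], -1)
        y = cols.reshape(b * oh * ow, -1) @ w2.T + self.b
        y = y.reshape(b, oh, ow, -1).transpose(0, 3, 1, 2)
        if self.relu:
            y = _relu(y)
        self._y = y
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self.relu:
            dy = dy * (self._y > 0)
        dy = dy.astype(self.dtype, copy=False)
        b, c, h, w = self._in_shape
        cols, (oh, ow, ph, pw, xp_shape) = self._cols, self._geom
        dyf = dy.transpose(0, 2, 3, 1).reshape(b * oh * ow, -1)
        w2 = self.w.reshape(self.w.shape[0], -1)
        self.dw[...] = (dyf.T @ cols.reshape(b * oh * ow, -1)).reshape(self.w.shape)
        self.db[...] = dyf.sum(axis=0)
        dcols = (dyf @ w2).reshape(b, oh, ow, c, self.k, self.k)
        dxp = np.zeros(xp_shape, dtype=self.dtype)
        s = self.stride
        for i in range(self.k):
            for j in range(self.k):
                dxp[:, :, i : i + s * oh : s, j : j + s * ow : s] += dcols[:, :, :, :, i, j].transpose(
                    0, 3, 1, 2
                )
        return dxp[:, :, ph[0] : ph[0] + h, pw[0] : pw[0] + w]


class Upsample2x(Layer):
    """Nearest-neighbour 2x spatial upsampling."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        b, c, h, w = self._shape
        return dy.reshape(b, c, h, 2, w, 2).sum(axis=(3, 5))


class Crop2d(Layer):
    """Crop spatial dimensions down to a target size (top-left anchored)."""

    def __init__(self, height: int, width: int):
        self.h = height
        self.w = width

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x[:, :, : self.h, : self.w]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = np.zeros(self._shape)
        dx[:, :, : self.h, : self.w] = dy
        return dx


class Dense(Layer):
    """Fully connected layer with optional ReLU; Glorot-scaled init."""

    def __init__(
        self,
        in_features: int,
        out_features: int,
        relu: bool = False,
        rng: np.random.Generator | None = None,
        dtype=np.float32,
    ):
        rng = rng or np.random.default_rng()
        scale = np.sqrt(2.0 / (in_features + out_features))
        self.dtype = np.dtype(dtype)
        self.w = (rng.standard_normal((in_features, out_features)) * scale).astype(self.dtype)
        self.b = np.zeros(out_features, dtype=self.dtype)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self.relu = relu

    def parameters(self):
        return [self.w, self.b]

    def gradients(self):
        return [self.dw, self.db]

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=self.dtype)
        self._x = x
        y = x @ self.w + self.b
        if self.relu:
            y = _relu(y)
        self._y = y
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self.relu:
            dy = dy * (self._y > 0)
        dy = dy.astype(self.dtype, copy=False)
        self.dw[...] = self._x.T @ dy
        self.db[...] = dy.sum(axis=0)
        return dy @ self.w.T


class Adam:
    """ADAM optimizer with the customary defaults (beta1 0.9, beta2 0.999)."""

    def __init__(
        self,
        params: list[np.ndarray],
        grads: list[np.ndarray],
        lr: float = 1e-4,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.params = params
        self.grads = grads
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, g, m, v in zip(self.params, self.grads, self.m, self.v):
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
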