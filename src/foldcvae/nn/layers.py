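"""Minimal feed-forward layers with explicit backpropagation.

Everything is plain NumPy. Convolutions are evaluated as a single BLAS
matmul per layer via an im2col lowering; transposed convolutions are the
exact linear adjoint of the matching convolution (same weight tensor
layout), so an encoder/decoder pair built from ``Conv2D`` and
``ConvTranspose2D`` with mirrored arguments is shape-symmetric by
construction.

Array layout is channels-first: ``(batch, channels, height, width)``.
Spatial padding follows the "same" convention: an output size of
``ceil(in / stride)`` with the excess padding placed on the bottom/right.
Inputs are assumed square (contact maps are M×M).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer",
    "Conv2D",
    "ConvTranspose2D",
    "Dense",
    "ReLU",
    "Flatten",
    "Reshape",
    "glorot_uniform",
]


def glorot_uniform(rng: np.random.Generator, shape, fan_in, fan_out, dtype):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


def _same_geometry(size: int, k: int, stride: int):
    """Output size and (before, after) padding for 'same' convolution."""
    out = -(-size // stride)
    total = max((out - 1) * stride + k - size, 0)
    return out, total // 2, total - total // 2


def _im2col(x: np.ndarray, k: int, stride: int, p0: int, p1: int) -> np.ndarray:
    """(B,C,H,W) -> (B, OH*OW, C*k*k) patch matrix."""
    b, c, h, _ = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (p0, p1), (p0, p1)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]  # (B,C,OH,OW,k,k)
    oh, ow = win.shape[2], win.shape[3]
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(b, oh * ow, c * k * k)
    return np.ascontiguousarray(cols), oh, ow


def _col2im(cols: np.ndarray, x_shape, k: int, stride: int, p0: int, p1: int,
            oh: int, ow: int) -> np.ndarray:
    """Adjoint of _im2col: scatter-add patches back onto the image grid."""
    b, c, h, w = x_shape
    acc = np.zeros((b, c, h + p0 + p1, w + p0 + p1), dtype=cols.dtype)
    patches = cols.reshape(b, oh, ow, c, k, k).transpose(0, 3, 1, 2, 4, 5)
    for i in range(k):
        for j in range(k):
            acc[:, :, i:i + oh * stride:stride, j:j + ow * stride:stride] += \
                patches[:, :, :, :, i, j]
    return acc[:, :, p0:h + p0, p0:w + p0]


class Layer:
    """Base: stateless apart from parameters, gradients and forward cache."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2D(Layer):
    """'Same'-padded 2-D convolution, weight shape (C_in*k*k, C_out)."""

    def __init__(self, c_in, c_out, k, stride, rng, dtype=np.float32):
        super().__init__()
        self.c_in, self.c_out, self.k, self.stride = c_in, c_out, k, stride
        fan_in, fan_out = c_in * k * k, c_out * k * k
        self.params["W"] = glorot_uniform(rng, (c_in * k * k, c_out),
                                          fan_in, fan_out, dtype)
        self.params["b"] = np.zeros(c_out, dtype=dtype)

    def forward(self, x):
        _, _, h, _ = x.shape
        _, p0, p1 = _same_geometry(h, self.k, self.stride)
        cols, oh, ow = _im2col(x, self.k, self.stride, p0, p1)
        self._cache = (cols, x.shape, p0, p1, oh, ow)
        y = cols @ self.params["W"] + self.params["b"]
        return y.transpose(0, 2, 1).reshape(x.shape[0], self.c_out, oh, ow)

    def backward(self, dy):
        cols, x_shape, p0, p1, oh, ow = self._cache
        b = dy.shape[0]
        dy2 = dy.reshape(b, self.c_out, oh * ow).transpose(0, 2, 1)
        flat_cols = cols.reshape(b * oh * ow, -1)
        flat_dy = np.ascontiguousarray(dy2).reshape(b * oh * ow, self.c_out)
        self.grads["W"] = flat_cols.T @ flat_dy
        self.grads["b"] = flat_dy.sum(axis=0)
        dcols = dy2 @ self.params["W"].T
        return _col2im(dcols, x_shape, self.k, self.stride, p0, p1, oh, ow)


class ConvTranspose2D(Layer):
    """Adjoint of a 'same'-padded Conv2D; upsamples by ``stride``.

    ``out_size`` fixes the output spatial size (needed because stride-s
    'same' convolution maps several input sizes onto the same output size).
    """

    def __init__(self, c_in, c_out, k, stride, out_size, rng, dtype=np.float32):
        super().__init__()
        self.c_in, self.c_out, self.k, self.stride = c_in, c_out, k, stride
        self.out_size = out_size
        self.in_size, self.p0, self.p1 = _same_geometry(out_size, k, stride)
        fan_in, fan_out = c_in * k * k, c_out * k * k
        # weight laid out as in the adjoint convolution: (C_out*k*k, C_in)
        self.params["W"] = glorot_uniform(rng, (c_out * k * k, c_in),
                                          fan_in, fan_out, dtype)
        self.params["b"] = np.zeros(c_out, dtype=dtype)

    def forward(self, x):
        b, c, h, w = x.shape
        if h != self.in_size:
            raise ValueError(f"expected input size {self.in_size}, got {h}")
        x2 = x.reshape(b, c, h * w).transpose(0, 2, 1)
        dcols = x2 @ self.params["W"].T
        out_shape = (b, self.c_out, self.out_size, self.out_size)
        y = _col2im(dcols, out_shape, self.k, self.stride, self.p0, self.p1, h, w)
        self._cache = (x2, h, w)
        return y + self.params["b"][None, :, None, None]

    def backward(self, dy):
        x2, h, w = self._cache
        b = dy.shape[0]
        cols, oh, ow = _im2col(dy, self.k, self.stride, self.p0, self.p1)
        flat_cols = cols.reshape(b * oh * ow, -1)
        flat_x = np.ascontiguousarray(x2).reshape(b * h * w, self.c_in)
        self.grads["W"] = flat_cols.T @ flat_x
        self.grads["b"] = dy.sum(axis=(0, 2, 3))
        dx2 = cols @ self.params["W"]
        return dx2.transpose(0, 2, 1).reshape(b, self.c_in, h, w)


class Dense(Layer):
    def __init__(self, n_in, n_out, rng, dtype=np.float32):
        super().__init__()
        self.params["W"] = glorot_uniform(rng, (n_in, n_out), n_in, n_out, dtype)
        self.params["b"] = np.zeros(n_out, dtype=dtype)

    def forward(self, x):
        self._cache = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy):
        x = self._cache
        self.grads["W"] = x.T @ dy
        self.grads["b"] = dy.sum(axis=0)
        return dy @ self.params["W"].T


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, 0)

    def backward(self, dy):
        return np.where(self._mask, dy, 0)


class Flatten(Layer):
    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Reshape(Layer):
    def __init__(self, shape):
        super().__init__()
        self.shape = shape  # per-sample shape

    def forward(self, x):
        return x.reshape((x.shape[0],) + self.shape)

    def backward(self, dy):
        return dy.reshape(dy.shape[0], -1)
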