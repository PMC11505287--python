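"""Minimal float32 CNN layer toolkit with hand-written backpropagation.

Layers follow a uniform contract: ``forward(x, train)`` caches what the
backward pass needs, ``backward(dy)`` accumulates parameter gradients and
returns the input gradient.  Convolutions use im2col + BLAS matmul; the
column matrix is recomputed in the backward pass instead of cached, trading
a little compute for a much smaller activation footprint.
"""

from __future__ import annotations

import numpy as np


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value.astype(np.float32)
        self.grad = np.zeros_like(self.value)


def _im2col3(x: np.ndarray) -> np.ndarray:
    """(N,C,H,W) -> (N, C*9, H*W) columns for a 3x3 same-padding convolution.

    Built from nine contiguous block copies (one per kernel offset), so the
    result is already in matmul-ready layout with no strided transposes.
    """
    n, c, h, w = x.shape
    xp = np.zeros((n, c, h + 2, w + 2), dtype=x.dtype)
    xp[:, :, 1:-1, 1:-1] = x
    cols = np.empty((n, c, 9, h, w), dtype=x.dtype)
    for di in range(3):
        for dj in range(3):
            cols[:, :, di * 3 + dj] = xp[:, :, di : di + h, dj : dj + w]
    return cols.reshape(n, c * 9, h * w)


def conv3x3_forward(
    x: np.ndarray, w: np.ndarray, b: np.ndarray | None, cols: np.ndarray | None = None
) -> np.ndarray:
    """x (N,C,H,W), w (Cout, C*9), b (Cout,) -> (N,Cout,H,W)."""
    n, c, h, wd = x.shape
    if cols is None:
        cols = _im2col3(x)
    y = np.matmul(w[None], cols)  # (N, Cout, H*W)
    if b is not None:
        y += b[None, :, None]
    return y.reshape(n, -1, h, wd)


def conv3x3_backward(
    x: np.ndarray, w: np.ndarray, dy: np.ndarray, cols: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gradients (dx, dw, db) for conv3x3_forward."""
    n, c, h, wd = x.shape
    if cols is None:
        cols = _im2col3(x)
    dy_flat = dy.reshape(n, -1, h * wd)
    dw = np.matmul(dy_flat, cols.transpose(0, 2, 1)).sum(axis=0)
    db = dy_flat.sum(axis=(0, 2))
    dcols = np.matmul(w.T[None], dy_flat).reshape(n, c, 9, h, wd)
    dxp = np.zeros((n, c, h + 2, wd + 2), dtype=x.dtype)
    for di in range(3):
        for dj in range(3):
            dxp[:, :, di : di + h, dj : dj + wd] += dcols[:, :, di * 3 + dj]
    return dxp[:, :, 1:-1, 1:-1], dw, db


class Conv3x3:
    """3x3 convolution, stride 1, same padding, He-initialized."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, bias: bool = True):
        std = np.sqrt(2.0 / (c_in * 9))
        self.w = Param(rng.normal(0, std, size=(c_out, c_in * 9)).astype(np.float32))
        self.b = Param(np.zeros(c_out, dtype=np.float32)) if bias else None
        self._x: np.ndarray | None = None
        self._cols: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        cols = _im2col3(x)
        if train:
            self._x = x
            self._cols = cols
        return conv3x3_forward(x, self.w.value, self.b.value if self.b else None, cols)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx, dw, db = conv3x3_backward(self._x, self.w.value, dy, self._cols)
        self.w.grad += dw
        if self.b is not None:
            self.b.grad += db
        self._x = None
        self._cols = None
        return dx

    def params(self) -> list[Param]:
        return [self.w] + ([self.b] if self.b else [])


class Conv1x1:
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        std = np.sqrt(2.0 / c_in)
        self.w = Param(rng.normal(0, std, size=(c_out, c_in)).astype(np.float32))
        self.b = Param(np.zeros(c_out, dtype=np.float32))
        self._x = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            self._x = x
        n, c, h, w = x.shape
        y = np.tensordot(self.w.value, x, axes=([1], [1]))  # (Cout, N, H, W)
        y = y.transpose(1, 0, 2, 3) + self.b.value[None, :, None, None]
        return np.ascontiguousarray(y)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._x
        self.w.grad += np.einsum("nchw,nkhw->ck", dy, x, optimize=True)
        self.b.grad += dy.sum(axis=(0, 2, 3))
        dx = np.tensordot(self.w.value.T, dy, axes=([1], [1])).transpose(1, 0, 2, 3)
        self._x = None
        return np.ascontiguousarray(dx)

    def params(self) -> list[Param]:
        return [self.w, self.b]


class BatchNorm2d:
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(c, dtype=np.float32))
        self.beta = Param(np.zeros(c, dtype=np.float32))
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mean
            ).astype(np.float32)
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * var
            ).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * invstd[None, :, None, None]
        if train:
            self._cache = (xhat.astype(np.float32), invstd.astype(np.float32))
        return (
            self.gamma.value[None, :, None, None] * xhat
            + self.beta.value[None, :, None, None]
        ).astype(np.float32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, invstd = self._cache
        self._cache = None
        m = dy.shape[0] * dy.shape[2] * dy.shape[3]
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dy.sum(axis=(0, 2, 3))
        g = self.gamma.value[None, :, None, None]
        dxhat = dy * g
        mean_dxhat = dxhat.mean(axis=(0, 2, 3), keepdims=True)
        mean_dxhat_xhat = (dxhat * xhat).mean(axis=(0, 2, 3), keepdims=True)
        dx = (dxhat - mean_dxhat - xhat * mean_dxhat_xhat) * invstd[None, :, None, None]
        return dx.astype(np.float32)

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]


class ReLU:
    def __init__(self):
        self._mask = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            self._mask = x > 0
        return np.maximum(x, 0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = dy * self._mask
        self._mask = None
        return dx

    def params(self) -> list:
        return []


class MaxPool2:
    """2x2 max pooling, stride 2 (H and W must be even)."""

    def __init__(self):
        self._idx = None
        self._shape = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xr = xr.reshape(n, c, h // 2, w // 2, 4)
        idx = xr.argmax(axis=-1)
        out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
        if train:
            self._idx = idx
            self._shape = (n, c, h, w)
        return np.ascontiguousarray(out)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        dxr = np.zeros((n, c, h // 2, w // 2, 4), dtype=dy.dtype)
        np.put_along_axis(dxr, self._idx[..., None], dy[..., None], axis=-1)
        dx = dxr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        self._idx = None
        return np.ascontiguousarray(dx.reshape(n, c, h, w))

    def params(self) -> list:
        return []


class ConvTranspose2:
    """2x2 transposed convolution with stride 2 (exact 2x upsampling)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        std = np.sqrt(2.0 / c_in)
        self.w = Param(rng.normal(0, std, size=(c_in, c_out, 2, 2)).astype(np.float32))
        self.b = Param(np.zeros(c_out, dtype=np.float32))
        self._x = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            self._x = x
        n, c, h, w = x.shape
        t = np.tensordot(x, self.w.value, axes=([1], [0]))  # (N,H,W,Cout,2,2)
        t = t.transpose(0, 3, 1, 4, 2, 5).reshape(n, -1, 2 * h, 2 * w)
        return np.ascontiguousarray(t + self.b.value[None, :, None, None])

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._x
        n, c, h, w = x.shape
        c_out = dy.shape[1]
        dyt = dy.reshape(n, c_out, h, 2, w, 2).transpose(0, 2, 4, 1, 3, 5)
        # dyt: (N,H,W,Cout,2,2)
        self.w.grad += np.tensordot(x, dyt, axes=([0, 2, 3], [0, 1, 2]))
        self.b.grad += dy.sum(axis=(0, 2, 3))
        dx = np.tensordot(dyt, self.w.value, axes=([3, 4, 5], [1, 2, 3]))
        self._x = None
        return np.ascontiguousarray(dx.transpose(0, 3, 1, 2))

    def params(self) -> list[Param]:
        return [self.w, self.b]


def sigmoid(x: np.ndarray) -> np.ndarray:
    from scipy.special import expit

    return expit(x)
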