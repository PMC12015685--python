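"""Minimal NHWC neural-network layers with explicit forward/backward passes.

Every layer caches what its backward pass needs during ``forward`` and
releases gradients into ``self.grads`` during ``backward``.  All parameters
and activations are float32; layout is channels-last (N, H, W, C).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

F32 = np.float32


class Layer:
    """Base class: stateless unless it declares ``params``."""

    trainable: bool = True

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool, rng=None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def n_params(self) -> int:
        return sum(int(p.size) for p in self.params.values())


class Conv2D(Layer):
    """2-D convolution, odd square kernel, zero 'same' padding, given stride.

    Implemented as im2col + one BLAS matmul per batch; backward reverses the
    gather with a per-kernel-offset scatter (k*k accumulations, vectorised).
    """

    def __init__(self, c_in: int, c_out: int, kernel: int = 3, stride: int = 1,
                 rng: np.random.Generator | None = None, init: str = "he") -> None:
        super().__init__()
        if kernel % 2 != 1:
            raise ValueError("kernel size must be odd")
        self.c_in, self.c_out, self.k, self.stride = c_in, c_out, kernel, stride
        rng = rng or np.random.default_rng()
        fan_in = kernel * kernel * c_in
        if init == "he":
            sd = np.sqrt(2.0 / fan_in)
        else:  # glorot
            sd = np.sqrt(2.0 / (fan_in + c_out))
        self.params = {
            "w": rng.normal(0.0, sd, size=(kernel * kernel * c_in, c_out)).astype(F32),
            "b": np.zeros(c_out, dtype=F32),
        }

    def forward(self, x, train, rng=None):
        k, s = self.k, self.stride
        pad = k // 2
        xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
        # (N, Ho, Wo, C, k, k) -> (N, Ho, Wo, k, k, C)
        win = sliding_window_view(xp, (k, k), axis=(1, 2))[:, ::s, ::s]
        cols = np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3), dtype=F32)
        n, ho, wo = cols.shape[:3]
        self._cache = (x.shape, cols.reshape(n * ho * wo, k * k * self.c_in))
        y = self._cache[1] @ self.params["w"] + self.params["b"]
        return y.reshape(n, ho, wo, self.c_out)

    def backward(self, dy):
        x_shape, cols = self._cache
        k, s = self.k, self.stride
        pad = k // 2
        n, h, w, _ = x_shape
        ho, wo = dy.shape[1], dy.shape[2]
        dy_flat = dy.reshape(-1, self.c_out).astype(F32)
        self.grads["w"] = cols.T @ dy_flat
        self.grads["b"] = dy_flat.sum(axis=0)
        dcols = (dy_flat @ self.params["w"].T).reshape(n, ho, wo, k, k, self.c_in)
        dxp = np.zeros((n, h + 2 * pad, w + 2 * pad, self.c_in), dtype=F32)
        for i in range(k):
            for j in range(k):
                dxp[:, i:i + s * ho:s, j:j + s * wo:s] += dcols[:, :, :, i, j]
        del self._cache
        return dxp[:, pad:pad + h, pad:pad + w]


class ConvTranspose2D(Layer):
    """Stride-2 transposed convolution (kernel 3) that exactly doubles H and W.

    Output pixel (2i+ki-1, 2j+kj-1) accumulates x[i,j] @ w[ki,kj]; equivalent
    to pad=1, output_padding=1 in framework conventions.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int = 3,
                 rng: np.random.Generator | None = None) -> None:
        super().__init__()
        self.c_in, self.c_out, self.k = c_in, c_out, kernel
        rng = rng or np.random.default_rng()
        sd = np.sqrt(2.0 / (kernel * kernel * c_in))
        self.params = {
            "w": rng.normal(0.0, sd, size=(kernel, kernel, c_in, c_out)).astype(F32),
            "b": np.zeros(c_out, dtype=F32),
        }

    def forward(self, x, train, rng=None):
        n, h, w, _ = x.shape
        k = self.k
        self._x = x
        full = np.zeros((n, 2 * h + k - 2, 2 * w + k - 2, self.c_out), dtype=F32)
        for ki in range(k):
            for kj in range(k):
                full[:, ki:ki + 2 * h - 1:2, kj:kj + 2 * w - 1:2] += (
                    x @ self.params["w"][ki, kj])
        pad = (k - 1) // 2
        return full[:, pad:pad + 2 * h, pad:pad + 2 * w] + self.params["b"]

    def backward(self, dy):
        x = self._x
        n, h, w, _ = x.shape
        k = self.k
        pad = (k - 1) // 2
        dfull = np.zeros((n, 2 * h + k - 2, 2 * w + k - 2, self.c_out), dtype=F32)
        dfull[:, pad:pad + 2 * h, pad:pad + 2 * w] = dy
        dw = np.empty_like(self.params["w"])
        dx = np.zeros_like(x)
        xf = x.reshape(-1, self.c_in)
        for ki in range(k):
            for kj in range(k):
                sl = dfull[:, ki:ki + 2 * h - 1:2, kj:kj + 2 * w - 1:2]
                dw[ki, kj] = xf.T @ sl.reshape(-1, self.c_out)
                dx += sl @ self.params["w"][ki, kj].T
        self.grads["w"] = dw
        self.grads["b"] = dy.reshape(-1, self.c_out).sum(axis=0)
        del self._x
        return dx


class MaxPool2(Layer):
    """2x2 max pooling, stride 2. Odd trailing rows/columns are dropped; a
    1-pixel map passes through unchanged (identity pool)."""

    def __init__(self) -> None:
        super().__init__()

    def forward(self, x, train, rng=None):
        n, h, w, c = x.shape
        if h < 2 or w < 2:
            self._identity = True
            return x
        self._identity = False
        ho, wo = h // 2, w // 2
        xc = x[:, :2 * ho, :2 * wo]
        blocks = xc.reshape(n, ho, 2, wo, 2, c)
        y = blocks.max(axis=(2, 4))
        self._cache = (x.shape, blocks, y)
        return y

    def backward(self, dy):
        if self._identity:
            return dy
        x_shape, blocks, y = self._cache
        n, h, w, c = x_shape
        ho, wo = h // 2, w // 2
        mask = blocks == y[:, :, None, :, None, :]
        # split gradient evenly among tied maxima so the pool stays exact-sum
        counts = mask.sum(axis=(2, 4), keepdims=True)
        dblocks = mask * (dy[:, :, None, :, None, :] / counts)
        dx = np.zeros(x_shape, dtype=F32)
        dx[:, :2 * ho, :2 * wo] = dblocks.reshape(n, 2 * ho, 2 * wo, c)
        del self._cache
        return dx


class GlobalAvgPool(Layer):
    """Mean over the spatial axes: (N, H, W, C) -> (N, C)."""

    def forward(self, x, train, rng=None):
        self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, dy):
        n, h, w, c = self._shape
        return np.broadcast_to(dy[:, None, None, :] / F32(h * w), self._shape).astype(F32)


class BatchNorm(Layer):
    """Batch normalisation over all axes but the last (channels)."""

    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5) -> None:
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.params = {"gamma": np.ones(c, dtype=F32), "beta": np.zeros(c, dtype=F32)}
        self.running_mean = np.zeros(c, dtype=F32)
        self.running_var = np.ones(c, dtype=F32)
        self.frozen = False  # frozen layers use running stats even in train mode

    def forward(self, x, train, rng=None):
        axes = tuple(range(x.ndim - 1))
        if train and not self.frozen:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean = (m * self.running_mean + (1 - m) * mean).astype(F32)
            self.running_var = (m * self.running_var + (1 - m) * var).astype(F32)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        self._cache = (xhat, inv.astype(F32), x.ndim, train and not self.frozen)
        return (self.params["gamma"] * xhat + self.params["beta"]).astype(F32)

    def backward(self, dy):
        xhat, inv, ndim, batch_stats = self._cache
        axes = tuple(range(ndim - 1))
        self.grads["gamma"] = (dy * xhat).sum(axis=axes)
        self.grads["beta"] = dy.sum(axis=axes)
        g = self.params["gamma"]
        if not batch_stats:
            return (dy * g * inv).astype(F32)
        m = np.prod([dy.shape[a] for a in axes])
        dxhat = dy * g
        dx = (dxhat - dxhat.mean(axis=axes)
              - xhat * (dxhat * xhat).mean(axis=axes)) * inv
        del self._cache
        return dx.astype(F32)


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float) -> None:
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate

    def forward(self, x, train, rng=None):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("training-mode dropout requires an rng stream")
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(F32) / F32(keep)
        return x * self._mask

    def backward(self, dy):
        if self._mask is None:
            return dy
        return dy * self._mask


class Flatten(Layer):
    def forward(self, x, train, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Reshape(Layer):
    """Reshape trailing dims of (N, D) to a fixed target, e.g. (H, W, C)."""

    def __init__(self, target: tuple[int, ...]) -> None:
        super().__init__()
        self.target = target

    def forward(self, x, train, rng=None):
        self._shape = x.shape
        return x.reshape((x.shape[0],) + self.target)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int,
                 rng: np.random.Generator | None = None, init: str = "he") -> None:
        super().__init__()
        rng = rng or np.random.default_rng()
        if init == "he":
            sd = np.sqrt(2.0 / d_in)
        else:
            sd = np.sqrt(2.0 / (d_in + d_out))
        self.params = {
            "w": rng.normal(0.0, sd, size=(d_in, d_out)).astype(F32),
            "b": np.zeros(d_out, dtype=F32),
        }

    def forward(self, x, train, rng=None):
        self._x = x
        return x @ self.params["w"] + self.params["b"]

    def backward(self, dy):
        self.grads["w"] = self._x.T @ dy
        self.grads["b"] = dy.sum(axis=0)
        dx = dy @ self.params["w"].T
        del self._x
        return dx


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.2) -> None:
        super().__init__()
        self.slope = F32(slope)

    def forward(self, x, train, rng=None):
        self._neg = x < 0
        return np.where(self._neg, self.slope * x, x)

    def backward(self, dy):
        return np.where(self._neg, self.slope * dy, dy)


class ReLU(Layer):
    def forward(self, x, train, rng=None):
        self._neg = x < 0
        return np.where(self._neg, F32(0), x)

    def backward(self, dy):
        return np.where(self._neg, F32(0), dy)


class Tanh(Layer):
    def forward(self, x, train, rng=None):
        self._y = np.tanh(x)
        return self._y

    def backward(self, dy):
        return dy * (1.0 - self._y * self._y)


class Sigmoid(Layer):
    def forward(self, x, train, rng=None):
        self._y = 1.0 / (1.0 + np.exp(-x.astype(np.float64)))
        return self._y.astype(F32)

    def backward(self, dy):
        return (dy * self._y * (1.0 - self._y)).astype(F32)
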