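"""Minimal 3D CNN building blocks on numpy.

Each layer stores its parameters and gradients and implements an explicit
``forward``/``backward`` pair.  Convolutions are stride-1 with 'same'
padding and are evaluated as a single BLAS matmul over an im2col view;
the input gradient is computed as a convolution with the spatially flipped,
channel-transposed kernel, so no scatter-add is needed.  Down/upsampling is
done by 2x max pooling and nearest-neighbor upsampling.

Arrays are ``(N, C, D, H, W)`` float32 throughout.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Layer",
    "Conv3d",
    "Linear",
    "LeakyReLU",
    "InstanceNorm3d",
    "BatchNorm1d",
    "MaxPool2x",
    "Upsample2x",
    "softmax_channels",
]


class Layer:
    """Base class: parameterized layers expose ``params`` and ``grads`` dicts."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    """(N, C, D, H, W) -> (N, L, C*k^3) columns of k-cubes, 'same' padding."""
    if pad:
        x = np.pad(x, ((0, 0), (0, 0)) + ((pad, pad),) * 3)
    win = sliding_window_view(x, (k, k, k), axis=(2, 3, 4))  # (N,C,D,H,W,k,k,k)
    n, c, d, h, w = win.shape[:5]
    cols = win.transpose(0, 2, 3, 4, 1, 5, 6, 7).reshape(n, d * h * w, c * k**3)
    return np.ascontiguousarray(cols, dtype=np.float32)


class Conv3d(Layer):
    """Stride-1 'same' 3D convolution (kernel size 1 or 3)."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator,
                 init: str = "kaiming_normal", leaky_slope: float = 0.01) -> None:
        super().__init__()
        self.c_in, self.c_out, self.k = c_in, c_out, k
        self.pad = k // 2
        fan_in = c_in * k**3
        gain = np.sqrt(2.0 / (1.0 + leaky_slope**2))
        if init == "kaiming_normal":
            w = rng.normal(0.0, gain / np.sqrt(fan_in), size=(c_out, fan_in))
        elif init == "kaiming_uniform":
            bound = gain * np.sqrt(3.0 / fan_in)
            w = rng.uniform(-bound, bound, size=(c_out, fan_in))
        else:
            raise ValueError(f"unknown init {init!r}")
        self.params = {"w": w.astype(np.float32), "b": np.zeros(c_out, dtype=np.float32)}
        self._cols: np.ndarray | None = None
        self._shape: tuple | None = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, d, h, w = x.shape
        cols = _im2col(x, self.k, self.pad)
        out = cols @ self.params["w"].T + self.params["b"]
        self._cols = cols if train else None
        self._shape = x.shape
        return out.reshape(n, d, h, w, self.c_out).transpose(0, 4, 1, 2, 3)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, _, d, h, w = self._shape
        dflat = dout.transpose(0, 2, 3, 4, 1).reshape(n, d * h * w, self.c_out)
        self.grads["w"] = np.einsum("nlo,nlc->oc", dflat, self._cols, optimize=True)
        self.grads["b"] = dflat.sum(axis=(0, 1))
        # dx = conv(dout, W flipped spatially, channels transposed)
        wk = self.params["w"].reshape(self.c_out, self.c_in, self.k, self.k, self.k)
        w_flip = wk[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4).reshape(
            self.c_in, self.c_out * self.k**3
        )
        cols_b = _im2col(dout.astype(np.float32), self.k, self.pad)
        dx = cols_b @ w_flip.T
        self._cols = None
        return dx.reshape(n, d, h, w, self.c_in).transpose(0, 4, 1, 2, 3)


class Linear(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 init: str = "kaiming_uniform", leaky_slope: float = 0.01) -> None:
        super().__init__()
        gain = np.sqrt(2.0 / (1.0 + leaky_slope**2))
        if init == "kaiming_uniform":
            bound = gain * np.sqrt(3.0 / n_in)
            w = rng.uniform(-bound, bound, size=(n_out, n_in))
        else:
            w = rng.normal(0.0, gain / np.sqrt(n_in), size=(n_out, n_in))
        self.params = {"w": w.astype(np.float32), "b": np.zeros(n_out, dtype=np.float32)}
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._x = x if train else None
        return x @ self.params["w"].T + self.params["b"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads["w"] = dout.T @ self._x
        self.grads["b"] = dout.sum(axis=0)
        return dout @ self.params["w"]


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.01) -> None:
        super().__init__()
        self.slope = slope
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        mask = x >= 0
        if train:
            self._mask = mask
        return np.where(mask, x, self.slope * x)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dout, self.slope * dout)


class InstanceNorm3d(Layer):
    """Per-sample, per-channel normalization over the spatial dimensions."""

    def __init__(self, c: int, eps: float = 1e-5) -> None:
        super().__init__()
        self.eps = eps
        self.params = {"gamma": np.ones(c, dtype=np.float32), "beta": np.zeros(c, dtype=np.float32)}
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        ax = (2, 3, 4)
        mean = x.mean(axis=ax, keepdims=True)
        var = x.var(axis=ax, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        if train:
            self._cache = (xhat, inv)
        g = self.params["gamma"][None, :, None, None, None]
        b = self.params["beta"][None, :, None, None, None]
        return (g * xhat + b).astype(np.float32)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        ax = (2, 3, 4)
        m = np.prod([dout.shape[a] for a in ax])
        self.grads["gamma"] = (dout * xhat).sum(axis=(0, 2, 3, 4))
        self.grads["beta"] = dout.sum(axis=(0, 2, 3, 4))
        dxhat = dout * self.params["gamma"][None, :, None, None, None]
        dx = (
            dxhat - dxhat.mean(axis=ax, keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=ax, keepdims=True)
        ) * inv
        self._cache = None
        return dx.astype(np.float32)


class BatchNorm1d(Layer):
    """Batch normalization for the fully connected regression head."""

    def __init__(self, n: int, eps: float = 1e-5, momentum: float = 0.1) -> None:
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.params = {"gamma": np.ones(n, dtype=np.float32), "beta": np.zeros(n, dtype=np.float32)}
        self.running_mean = np.zeros(n, dtype=np.float32)
        self.running_var = np.ones(n, dtype=np.float32)
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            mean = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        if train:
            self._cache = (xhat, inv)
        return (self.params["gamma"] * xhat + self.params["beta"]).astype(np.float32)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        n = dout.shape[0]
        self.grads["gamma"] = (dout * xhat).sum(axis=0)
        self.grads["beta"] = dout.sum(axis=0)
        dxhat = dout * self.params["gamma"]
        dx = (dxhat - dxhat.mean(axis=0) - xhat * (dxhat * xhat).mean(axis=0)) * inv
        self._cache = None
        return dx.astype(np.float32)


class MaxPool2x(Layer):
    def __init__(self) -> None:
        super().__init__()
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, d, h, w = x.shape
        xr = x.reshape(n, c, d // 2, 2, h // 2, 2, w // 2, 2)
        out = xr.max(axis=(3, 5, 7))
        if train:
            up = np.repeat(np.repeat(np.repeat(out, 2, axis=2), 2, axis=3), 2, axis=4)
            self._cache = (x == up, x.shape)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        mask, shape = self._cache
        dup = np.repeat(np.repeat(np.repeat(dout, 2, axis=2), 2, axis=3), 2, axis=4)
        self._cache = None
        return np.where(mask, dup, 0.0).astype(np.float32)


class Upsample2x(Layer):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return np.repeat(np.repeat(np.repeat(x, 2, axis=2), 2, axis=3), 2, axis=4)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, d, h, w = dout.shape
        return dout.reshape(n, c, d // 2, 2, h // 2, 2, w // 2, 2).sum(axis=(3, 5, 7))


def softmax_channels(logits: np.ndarray) -> np.ndarray:
    """Numerically stable softmax over the channel axis of (N, C, ...)."""
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)
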