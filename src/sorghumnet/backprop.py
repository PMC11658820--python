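"""Minimal CPU neural-network engine (NumPy, NHWC layout).

Implements exactly the layer set the multicolumn counting network needs —
same-padded 2-D convolution (im2col + BLAS matmul), batch normalization,
ReLU, 2x2/stride-2 max pooling, nearest/bilinear upsampling — with
hand-derived backward passes and an Adam optimizer.  Everything is
deterministic given the initialization seed and single-threaded BLAS.

Tensors are float64 ``(N, H, W, C)``.  Layers cache what their backward
pass needs only when ``train=True`` is passed to ``forward``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import ValidationError

__all__ = [
    "Param",
    "Layer",
    "Conv2D",
    "BatchNorm",
    "ReLU",
    "MaxPool2x2",
    "Upsample",
    "Adam",
]


@dataclass
class Param:
    """A named array owned by a layer.  ``trainable=False`` marks batch-norm
    running statistics, which count as parameters under the framework
    convention used for the printed model sizes."""

    name: str
    value: np.ndarray
    grad: np.ndarray | None = None
    trainable: bool = True

    @property
    def count(self) -> int:
        return int(self.value.size)


class Layer:
    name: str = ""

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2D(Layer):
    """Same-padded, stride-1 2-D convolution.

    Weights are (k, k, c_in, c_out), He-initialized.  Forward extracts
    k*k*c_in patches with stride tricks and performs one matmul per batch,
    so the heavy lifting stays inside BLAS.
    """

    def __init__(self, c_in: int, c_out: int, kernel_size: int,
                 rng: np.random.Generator, name: str = "conv",
                 needs_input_grad: bool = True):
        if kernel_size < 1 or kernel_size % 2 == 0:
            raise ValidationError(f"kernel_size must be odd and >= 1, got {kernel_size}")
        self.name = name
        # layers fed directly by the image can skip the (expensive) dx pass
        self.needs_input_grad = needs_input_grad
        self.k = kernel_size
        self.c_in = c_in
        self.c_out = c_out
        std = np.sqrt(2.0 / (kernel_size * kernel_size * c_in))
        self.w = Param(f"{name}/kernel",
                       rng.normal(0.0, std, size=(kernel_size, kernel_size, c_in, c_out)))
        self.b = Param(f"{name}/bias", np.zeros(c_out))
        self._cols: np.ndarray | None = None
        self._xshape: tuple | None = None

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, h, w, c = x.shape
        if c != self.c_in:
            raise ValidationError(f"{self.name}: expected {self.c_in} channels, got {c}")
        k, p = self.k, self.k // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0))) if p else x
        # (N, H, W, C, k, k) -> (N*H*W, k*k*C) matching w.reshape(k*k*c_in, c_out)
        view = sliding_window_view(xp, (k, k), axis=(1, 2))
        cols = np.ascontiguousarray(view.transpose(0, 1, 2, 4, 5, 3)).reshape(
            n * h * w, k * k * c
        )
        y = cols @ self.w.value.reshape(k * k * c, self.c_out) + self.b.value
        if train:
            self._cols = cols
            self._xshape = x.shape
        return y.reshape(n, h, w, self.c_out)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._cols is None:
            raise RuntimeError(f"{self.name}: backward before forward(train=True)")
        n, h, w, _ = dy.shape
        k, p, c = self.k, self.k // 2, self.c_in
        dyf = dy.reshape(n * h * w, self.c_out)
        self.w.grad = (self._cols.T @ dyf).reshape(self.w.value.shape)
        self.b.grad = dyf.sum(axis=0)
        self._cols = None
        if not self.needs_input_grad:
            return np.empty(0, dtype=dy.dtype)
        dcols = (dyf @ self.w.value.reshape(k * k * c, self.c_out).T).reshape(
            n, h, w, k, k, c
        )
        dxp = np.zeros((n, h + 2 * p, w + 2 * p, c), dtype=dy.dtype)
        for i in range(k):
            for j in range(k):
                dxp[:, i:i + h, j:j + w, :] += dcols[:, :, :, i, j, :]
        return dxp[:, p:p + h, p:p + w, :] if p else dxp


class BatchNorm(Layer):
    """Per-channel batch normalization over (N, H, W).

    Running mean/variance (updated with ``momentum``) are used in eval mode
    and are exposed as non-trainable statistic parameters.  The default
    momentum 0.9 lets the running statistics converge within a few hundred
    optimizer steps, so eval-mode predictions are calibrated even for short
    CPU training schedules.
    """

    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-3,
                 name: str = "bn"):
        self.name = name
        self.eps = eps
        self.momentum = momentum
        self.gamma = Param(f"{name}/gamma", np.ones(c))
        self.beta = Param(f"{name}/beta", np.zeros(c))
        self.running_mean = Param(f"{name}/moving_mean", np.zeros(c), trainable=False)
        self.running_var = Param(f"{name}/moving_variance", np.ones(c), trainable=False)
        self._cache: tuple | None = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta, self.running_mean, self.running_var]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            m = self.momentum
            self.running_mean.value = m * self.running_mean.value + (1 - m) * mean
            self.running_var.value = m * self.running_var.value + (1 - m) * var
        else:
            mean = self.running_mean.value
            var = self.running_var.value
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        if train:
            self._cache = (xhat, inv)
        return self.gamma.value * xhat + self.beta.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._cache is None:
            raise RuntimeError(f"{self.name}: backward before forward(train=True)")
        xhat, inv = self._cache
        m = float(np.prod(dy.shape[:3]))
        self.gamma.grad = (dy * xhat).sum(axis=(0, 1, 2))
        self.beta.grad = dy.sum(axis=(0, 1, 2))
        dxhat = dy * self.gamma.value
        dx = (inv / m) * (
            m * dxhat
            - dxhat.sum(axis=(0, 1, 2))
            - xhat * (dxhat * xhat).sum(axis=(0, 1, 2))
        )
        self._cache = None
        return dx


class ReLU(Layer):
    def __init__(self, name: str = "relu"):
        self.name = name
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        y = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._mask is None:
            raise RuntimeError(f"{self.name}: backward before forward(train=True)")
        dx = dy * self._mask
        self._mask = None
        return dx


class MaxPool2x2(Layer):
    """2x2 max pooling with stride 2.  Ties propagate gradient to every
    maximal element of the window (measure-zero event for real activations)."""

    def __init__(self, name: str = "pool"):
        self.name = name
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, h, w, c = x.shape
        if h % 2 or w % 2:
            raise ValidationError(f"{self.name}: spatial dims must be even, got {h}x{w}")
        xr = x.reshape(n, h // 2, 2, w // 2, 2, c)
        y = xr.max(axis=(2, 4))
        if train:
            self._cache = (xr, y)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._cache is None:
            raise RuntimeError(f"{self.name}: backward before forward(train=True)")
        xr, y = self._cache
        mask = xr == y[:, :, None, :, None, :]
        dx = mask * dy[:, :, None, :, None, :]
        self._cache = None
        n, hh, _, ww, _, c = xr.shape
        return dx.reshape(n, hh * 2, ww * 2, c)


def _bilinear_matrix(n_out: int, n_in: int) -> np.ndarray:
    """Dense 1-D bilinear interpolation matrix (align_corners=False)."""
    a = np.zeros((n_out, n_in))
    scale = n_in / n_out
    src = (np.arange(n_out) + 0.5) * scale - 0.5
    src = np.clip(src, 0, n_in - 1)
    lo = np.floor(src).astype(int)
    hi = np.minimum(lo + 1, n_in - 1)
    frac = src - lo
    a[np.arange(n_out), lo] += 1 - frac
    a[np.arange(n_out), hi] += frac
    return a


class Upsample(Layer):
    """Integer-factor spatial upsampling, nearest (default) or bilinear."""

    def __init__(self, factor: int, mode: str = "nearest", name: str = "up"):
        if mode not in ("nearest", "bilinear"):
            raise ValidationError(f"unknown upsample mode {mode!r}")
        self.name = name
        self.factor = int(factor)
        self.mode = mode
        self._in_hw: tuple | None = None
        self._mats: dict[tuple, tuple[np.ndarray, np.ndarray]] = {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        f = self.factor
        if train:
            self._in_hw = x.shape[1:3]
        if self.mode == "nearest":
            return np.repeat(np.repeat(x, f, axis=1), f, axis=2)
        h, w = x.shape[1:3]
        key = (h, w)
        if key not in self._mats:
            self._mats[key] = (
                _bilinear_matrix(h * f, h).astype(x.dtype),
                _bilinear_matrix(w * f, w).astype(x.dtype),
            )
        ah, aw = self._mats[key]
        y = np.einsum("oh,nhwc->nowc", ah, x, optimize=True)
        return np.einsum("pw,nowc->nopc", aw, y, optimize=True)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        f = self.factor
        if self.mode == "nearest":
            n, hf, wf, c = dy.shape
            return dy.reshape(n, hf // f, f, wf // f, f, c).sum(axis=(2, 4))
        h, w = self._in_hw
        ah, aw = self._mats[(h, w)]
        dx = np.einsum("pw,nopc->nowc", aw, dy, optimize=True)
        return np.einsum("oh,nowc->nhwc", ah, dx, optimize=True)


class Adam:
    """Adam optimizer over a flat list of trainable parameters."""

    def __init__(self, params: list[Param], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.params = [p for p in params if p.trainable]
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self._m = [np.zeros_like(p.value) for p in self.params]
        self._v = [np.zeros_like(p.value) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1 - b1 ** self.t
        bc2 = 1 - b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                raise RuntimeError(f"parameter {p.name} has no gradient")
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad ** 2
            p.value -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
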