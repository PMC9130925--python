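"""Minimal 3D CNN building blocks with explicit forward/backward passes.

Tensors are NCDHW float64 numpy arrays. Every layer caches what its backward
pass needs during ``forward(..., training=True)``; ``backward(dout)``
accumulates parameter gradients in-place and returns the input gradient.
Parameters carry a ``kind`` tag ("weight", "bias", "norm") used by the
optimizer for weight-decay exemption and per-group gradient clipping.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Param",
    "Layer",
    "Conv3d",
    "ConvTranspose3d",
    "BatchNorm3d",
    "ReLU",
    "AvgPool3d",
    "Sequential",
    "ConvBlock",
]


class Param:
    """A trainable tensor plus its gradient accumulator and group tag."""

    __slots__ = ("value", "grad", "kind", "name")

    def __init__(self, value: np.ndarray, kind: str = "weight", name: str = ""):
        if kind not in ("weight", "bias", "norm"):
            raise ValueError(f"unknown param kind {kind!r}")
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)
        self.kind = kind
        self.name = name

    def zero_grad(self):
        self.grad[...] = 0.0


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def __call__(self, x, training=False):
        return self.forward(x, training=training)


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Conv3d(Layer):
    """3D convolution, odd kernel, stride 1, zero 'same' padding."""

    def __init__(self, c_in: int, c_out: int, kernel_size: int = 3,
                 rng: np.random.Generator | None = None, name: str = ""):
        if kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd")
        rng = np.random.default_rng(0) if rng is None else rng
        k = kernel_size
        fan_in = c_in * k ** 3
        self.k = k
        self.pad = (k - 1) // 2
        self.weight = Param(_he_init(rng, (c_out, c_in, k, k, k), fan_in),
                            "weight", f"{name}.weight")
        self.bias = Param(np.zeros(c_out), "bias", f"{name}.bias")
        self._xp = None

    def params(self):
        return [self.weight, self.bias]

    def zero_init(self):
        """Zero weights and bias (used to make residual heads start at identity)."""
        self.weight.value[...] = 0.0
        self.bias.value[...] = 0.0

    def _windows(self, xp):
        # (B, C, D, H, W, k, k, k)
        return sliding_window_view(xp, (self.k, self.k, self.k), axis=(2, 3, 4))

    def forward(self, x, training=False):
        p = self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
        win = self._windows(xp)
        out = np.einsum("bcdhwxyz,ocxyz->bodhw", win, self.weight.value,
                        optimize=True)
        out += self.bias.value[None, :, None, None, None]
        if training:
            self._xp = xp
        return out

    def backward(self, dout):
        if self._xp is None:
            raise RuntimeError("backward called before forward(training=True)")
        p = self.pad
        win = self._windows(self._xp)
        self.weight.grad += np.einsum("bodhw,bcdhwxyz->ocxyz", dout, win,
                                      optimize=True)
        self.bias.grad += dout.sum(axis=(0, 2, 3, 4))
        # gradient w.r.t. padded input: full convolution of dout with the
        # spatially flipped, channel-transposed kernel
        w_flip = self.weight.value[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4)
        q = self.k - 1
        dp = np.pad(dout, ((0, 0), (0, 0), (q, q), (q, q), (q, q)))
        dwin = sliding_window_view(dp, (self.k, self.k, self.k), axis=(2, 3, 4))
        dxp = np.einsum("bcdhwxyz,ocxyz->bodhw", dwin, w_flip, optimize=True)
        self._xp = None
        if p:
            return np.ascontiguousarray(dxp[:, :, p:-p, p:-p, p:-p])
        return dxp


class ConvTranspose3d(Layer):
    """2x upsampling transposed convolution (kernel 2, stride 2)."""

    def __init__(self, c_in: int, c_out: int,
                 rng: np.random.Generator | None = None, name: str = ""):
        rng = np.random.default_rng(0) if rng is None else rng
        self.weight = Param(_he_init(rng, (c_in, c_out, 2, 2, 2), c_in),
                            "weight", f"{name}.weight")
        self.bias = Param(np.zeros(c_out), "bias", f"{name}.bias")
        self._x = None

    def params(self):
        return [self.weight, self.bias]

    def forward(self, x, training=False):
        B, C, D, H, W = x.shape
        out = np.einsum("bcdhw,coxyz->bodxhywz", x, self.weight.value,
                        optimize=True)
        out = out.reshape(B, -1, 2 * D, 2 * H, 2 * W)
        out += self.bias.value[None, :, None, None, None]
        if training:
            self._x = x
        return out

    def backward(self, dout):
        x = self._x
        B, C, D, H, W = x.shape
        d6 = dout.reshape(dout.shape[0], dout.shape[1], D, 2, H, 2, W, 2)
        self.weight.grad += np.einsum("bcdhw,bodxhywz->coxyz", x, d6,
                                      optimize=True)
        self.bias.grad += dout.sum(axis=(0, 2, 3, 4))
        dx = np.einsum("bodxhywz,coxyz->bcdhw", d6, self.weight.value,
                       optimize=True)
        self._x = None
        return dx


class BatchNorm3d(Layer):
    """Per-channel batch normalization over (batch, spatial) axes."""

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5,
                 name: str = ""):
        self.gamma = Param(np.ones(c), "norm", f"{name}.gamma")
        self.beta = Param(np.zeros(c), "norm", f"{name}.beta")
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, training=False):
        if training:
            axes = (0, 2, 3, 4)
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None, None]) \
            * inv_std[None, :, None, None, None]
        if training:
            self._cache = (xhat, inv_std)
        return self.gamma.value[None, :, None, None, None] * xhat \
            + self.beta.value[None, :, None, None, None]

    def backward(self, dout):
        xhat, inv_std = self._cache
        axes = (0, 2, 3, 4)
        m = dout.shape[0] * dout.shape[2] * dout.shape[3] * dout.shape[4]
        self.gamma.grad += (dout * xhat).sum(axis=axes)
        self.beta.grad += dout.sum(axis=axes)
        g = self.gamma.value[None, :, None, None, None]
        dxhat = dout * g
        s1 = dxhat.sum(axis=axes)[None, :, None, None, None]
        s2 = (dxhat * xhat).sum(axis=axes)[None, :, None, None, None]
        dx = (dxhat - s1 / m - xhat * s2 / m) * inv_std[None, :, None, None, None]
        self._cache = None
        return dx


class ReLU(Layer):
    def __init__(self):
        self._mask = None

    def forward(self, x, training=False):
        out = np.maximum(x, 0.0)
        if training:
            self._mask = x > 0
        return out

    def backward(self, dout):
        dx = dout * self._mask
        self._mask = None
        return dx


class AvgPool3d(Layer):
    """2x average pooling; spatial dims must be even."""

    def forward(self, x, training=False):
        B, C, D, H, W = x.shape
        if D % 2 or H % 2 or W % 2:
            raise ValueError(f"AvgPool3d needs even spatial dims, got {x.shape}")
        return x.reshape(B, C, D // 2, 2, H // 2, 2, W // 2, 2).mean(axis=(3, 5, 7))

    def backward(self, dout):
        up = np.repeat(np.repeat(np.repeat(dout, 2, axis=2), 2, axis=3), 2, axis=4)
        return up / 8.0


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x, training=False):
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout


def ConvBlock(c_in: int, c_out: int, kernel_size: int = 3,
              rng: np.random.Generator | None = None, name: str = "") -> Sequential:
    """conv -> batch norm -> rectifier, the workhorse block of both stages."""
    return Sequential(
        Conv3d(c_in, c_out, kernel_size, rng=rng, name=f"{name}.conv"),
        BatchNorm3d(c_out, name=f"{name}.bn"),
        ReLU(),
    )
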