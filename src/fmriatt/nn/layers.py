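"""Layer modules with explicit backward passes."""

from __future__ import annotations

import numpy as np

from .core import Module, Parameter
from .functional import (
    _as_triple,
    conv3d_backward,
    conv3d_forward,
    resize_linear,
    resize_linear_backward,
)


def fan_in_uniform(rng: np.random.Generator, shape, fan_in: int, dtype=np.float32):
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(dtype)


class Conv3d(Module):
    """Strided 3D cross-correlation, channels-last, "same"-style default padding."""

    def __init__(
        self,
        c_in: int,
        c_out: int,
        kernel=3,
        stride: int = 1,
        padding="same",
        bias: bool = True,
        rng: np.random.Generator | None = None,
        dtype=np.float32,
    ):
        super().__init__()
        kh, kw, kd = _as_triple(kernel)
        if padding == "same":
            padding = ((kh - 1) // 2, (kw - 1) // 2, (kd - 1) // 2)
        self.stride = int(stride)
        self.padding = _as_triple(padding)
        rng = rng or np.random.default_rng()
        fan_in = kh * kw * kd * c_in
        self.weight = Parameter(
            fan_in_uniform(rng, (kh, kw, kd, c_in, c_out), fan_in, dtype)
        )
        self.bias = Parameter(np.zeros(c_out, dtype=dtype)) if bias else None

    def forward(self, x):
        b = self.bias.data if self.bias is not None else None
        out, self._cache = conv3d_forward(x, self.weight.data, b, self.stride, self.padding)
        return out

    def backward(self, gout):
        gx, gw, gb = conv3d_backward(gout, self.weight.data, self._cache)
        self.weight.accumulate(gw)
        if self.bias is not None:
            self.bias.accumulate(gb)
        return gx


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator | None = None,
                 dtype=np.float32):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.weight = Parameter(fan_in_uniform(rng, (n_in, n_out), n_in, dtype))
        self.bias = Parameter(np.zeros(n_out, dtype=dtype))

    def forward(self, x):
        self._x = x
        return x @ self.weight.data + self.bias.data

    def backward(self, gout):
        self.weight.accumulate(self._x.T @ gout)
        self.bias.accumulate(gout.sum(axis=0))
        return gout @ self.weight.data.T


class BatchNorm(Module):
    """Normalization over batch and spatial axes, per channel (last axis)."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1,
                 dtype=np.float32):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = Parameter(np.ones(channels, dtype=dtype))
        self.beta = Parameter(np.zeros(channels, dtype=dtype))
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)

    def _buffers(self):
        return {"running_mean": self.running_mean, "running_var": self.running_var}

    def forward(self, x):
        axes = tuple(range(x.ndim - 1))
        if self.training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mean
            self.running_var = (1 - m) * self.running_var + m * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        self._cache = (xhat, inv, axes, x.shape)
        return self.gamma.data * xhat + self.beta.data

    def backward(self, gout):
        xhat, inv, axes, shape = self._cache
        self.gamma.accumulate((gout * xhat).sum(axis=axes))
        self.beta.accumulate(gout.sum(axis=axes))
        g = gout * self.gamma.data
        if self.training:
            n = np.prod([shape[a] for a in axes])
            gx = (
                g - g.mean(axis=axes) - xhat * (g * xhat).mean(axis=axes)
            ) * inv
            _ = n  # batch size folded into the means above
        else:
            gx = g * inv
        return gx


class ReLU(Module):
    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, gout):
        return np.where(self._mask, gout, 0.0)


class Sigmoid(Module):
    def forward(self, x):
        out = np.empty_like(x)
        pos = x >= 0
        out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
        ex = np.exp(x[~pos])
        out[~pos] = ex / (1.0 + ex)
        self._out = out
        return out

    def backward(self, gout):
        return gout * self._out * (1.0 - self._out)


class MaxPool3d(Module):
    """2x2x2 max pooling with stride 2; odd extents are padded with -inf."""

    def forward(self, x):
        n, h, w, d, c = x.shape
        ph, pw, pd = h % 2, w % 2, d % 2
        if ph or pw or pd:
            x = np.pad(
                x,
                ((0, 0), (0, ph), (0, pw), (0, pd), (0, 0)),
                constant_values=-np.inf,
            )
        n, h, w, d, c = x.shape
        r = x.reshape(n, h // 2, 2, w // 2, 2, d // 2, 2, c)
        out = r.max(axis=(2, 4, 6))
        sel = r == out[:, :, None, :, None, :, None, :]
        cnt = sel.sum(axis=(2, 4, 6), keepdims=True)
        self._cache = (sel / cnt, x.shape, (ph, pw, pd))
        return out

    def backward(self, gout):
        frac, padded_shape, (ph, pw, pd) = self._cache
        g = frac * gout[:, :, None, :, None, :, None, :]
        g = g.reshape(padded_shape)
        n, h, w, d, c = padded_shape
        return g[:, : h - ph, : w - pw, : d - pd]


class Upsample3d(Module):
    """Trilinear resize of the three spatial axes to an explicit target shape."""

    def __init__(self, target_shape):
        super().__init__()
        self.target_shape = tuple(int(s) for s in target_shape)

    def forward(self, x):
        self._src_shape = x.shape
        return resize_linear(x, self.target_shape, axes=(1, 2, 3))

    def backward(self, gout):
        return resize_linear_backward(gout, self._src_shape, axes=(1, 2, 3))


class GlobalAvgPool(Module):
    """Mean over all spatial axes -> (n, c)."""

    def forward(self, x):
        self._shape = x.shape
        return x.mean(axis=tuple(range(1, x.ndim - 1)))

    def backward(self, gout):
        shape = self._shape
        spatial = int(np.prod(shape[1:-1]))
        g = gout.reshape(shape[0], *([1] * (len(shape) - 2)), shape[-1])
        return np.broadcast_to(g / spatial, shape).copy()
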