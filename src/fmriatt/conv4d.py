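"""Decomposed 4D convolution for fMRI series.

A 4D kernel ``K ∈ R^{kl×kh×kw×kd×c_in×c_out}`` is applied to a feature map
``x ∈ R^{l×h×w×d×c}`` by looping a native 3D convolution over temporal taps:
output frame ``j`` is ``Σ_i Conv3D(K_i, x_{j·st+i})``, so the temporal axis is
reduced like any strided valid-mode convolution, ``l_out = ⌊(l−kl)/st⌋ + 1``.
After the 4D layer the temporal axis is squeezed and flattened into the
channel axis so that downstream stages are purely 3D.

Convolutions are cross-correlations (no kernel flip), the mainstream
deep-learning convention.  ``conv4d_naive`` re-derives the same operation with
explicit loops over output positions and is kept free of any convolution
primitive: it is the oracle the decomposed path is tested against.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np

from .nn.core import Module, Parameter
from .nn.functional import _as_triple, conv3d_backward, conv3d_forward
from .nn.layers import fan_in_uniform


@dataclass
class Conv4DSpec:
    """Stride/padding plan for one 4D convolution layer.

    st: temporal stride; spatial_stride: stride of the inner 3D convolution
    (2 halves the grid); spatial_padding: per-axis voxels, or "same" for
    (k−1)/2 so odd kernels preserve spatial extent before striding.
    """

    st: int = 2
    spatial_stride: int = 2
    spatial_padding: tuple | str = "same"

    def __post_init__(self):
        if self.st < 1:
            raise ValueError("temporal stride st must be >= 1")
        if self.spatial_stride < 1:
            raise ValueError("spatial stride must be >= 1")

    def resolved_padding(self, spatial_kernel) -> tuple[int, int, int]:
        if self.spatial_padding == "same":
            return tuple((k - 1) // 2 for k in spatial_kernel)
        return _as_triple(self.spatial_padding)


@dataclass
class Kernel4D:
    """Weight bank (kl, kh, kw, kd, c_in, c_out) with optional per-output bias."""

    weights: np.ndarray
    bias: np.ndarray | None = None

    def __post_init__(self):
        self.weights = np.asarray(self.weights)
        if self.weights.ndim != 6:
            raise ValueError("Kernel4D weights must have 6 axes (kl,kh,kw,kd,ci,co)")
        kl, kh, kw, kd = self.weights.shape[:4]
        if kl < 1:
            raise ValueError("temporal kernel length kl must be >= 1")
        if any(k % 2 == 0 for k in (kh, kw, kd)):
            raise ValueError("spatial kernel extents must be odd")
        if self.bias is not None:
            self.bias = np.asarray(self.bias)
            if self.bias.shape != (self.weights.shape[5],):
                raise ValueError("bias must have one entry per output channel")

    @classmethod
    def init(cls, kl: int, spatial, c_in: int, c_out: int,
             rng: np.random.Generator, bias: bool = True, dtype=np.float32):
        kh, kw, kd = _as_triple(spatial)
        fan_in = kl * kh * kw * kd * c_in
        w = fan_in_uniform(rng, (kl, kh, kw, kd, c_in, c_out), fan_in, dtype)
        b = np.zeros(c_out, dtype=dtype) if bias else None
        return cls(w, b)


def temporal_out_len(l: int, kl: int, st: int) -> int:
    if l < kl:
        raise ValueError(f"temporal underflow: input has {l} frames, kernel needs {kl}")
    return (l - kl) // st + 1


def conv4d_decomposed(x: np.ndarray, k: Kernel4D, spec: Conv4DSpec) -> np.ndarray:
    """4D convolution of an unbatched map (l,h,w,d,c) via looped 3D convolution."""
    x = np.asarray(x)
    if x.ndim != 5:
        raise ValueError("input must have 5 axes (l,h,w,d,c)")
    kl = k.weights.shape[0]
    l_out = temporal_out_len(x.shape[0], kl, spec.st)
    pad = spec.resolved_padding(k.weights.shape[1:4])
    frames = []
    for j in range(l_out):
        acc = None
        for i in range(kl):
            out, _ = conv3d_forward(
                x[None, j * spec.st + i], k.weights[i], None,
                spec.spatial_stride, pad,
            )
            acc = out if acc is None else acc + out
        if k.bias is not None:
            acc = acc + k.bias
        frames.append(acc[0])
    return np.stack(frames, axis=0)


def conv4d_naive(x: np.ndarray, k: Kernel4D, spec: Conv4DSpec) -> np.ndarray:
    """Brute-force 4D cross-correlation: explicit loops over every output
    position and kernel tap; no convolution primitive involved."""
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 5:
        raise ValueError("input must have 5 axes (l,h,w,d,c)")
    kl, kh, kw, kd, c_in, c_out = k.weights.shape
    if x.shape[4] != c_in:
        raise ValueError(
            f"channel mismatch: input has {x.shape[4]} channels, kernel expects {c_in}"
        )
    l_out = temporal_out_len(x.shape[0], kl, spec.st)
    ph, pw, pd = spec.resolved_padding((kh, kw, kd))
    xp = np.pad(x, ((0, 0), (ph, ph), (pw, pw), (pd, pd), (0, 0)))
    s = spec.spatial_stride
    ho = (xp.shape[1] - kh) // s + 1
    wo = (xp.shape[2] - kw) // s + 1
    do = (xp.shape[3] - kd) // s + 1
    if min(ho, wo, do) < 1:
        raise ValueError("spatial extent smaller than kernel after padding")
    w = np.asarray(k.weights, dtype=np.float64)
    out = np.zeros((l_out, ho, wo, do, c_out))
    for j, oh, ow, od in product(range(l_out), range(ho), range(wo), range(do)):
        window = xp[
            j * spec.st : j * spec.st + kl,
            oh * s : oh * s + kh,
            ow * s : ow * s + kw,
            od * s : od * s + kd,
            :,
        ]
        for co in range(c_out):
            out[j, oh, ow, od, co] = np.sum(window * w[..., co])
    if k.bias is not None:
        out += k.bias
    return out


def squeeze_flatten_time(x: np.ndarray) -> np.ndarray:
    """(l,h,w,d,c) -> (h,w,d,l·c); channel block t holds frame t's channels."""
    x = np.asarray(x)
    l, h, w, d, c = x.shape
    return np.ascontiguousarray(x.transpose(1, 2, 3, 0, 4)).reshape(h, w, d, l * c)


def unflatten_time(y: np.ndarray, l: int) -> np.ndarray:
    """Inverse of :func:`squeeze_flatten_time`."""
    h, w, d, lc = y.shape
    if lc % l:
        raise ValueError(f"channel extent {lc} not divisible by l={l}")
    return np.ascontiguousarray(
        y.reshape(h, w, d, l, lc // l).transpose(3, 0, 1, 2, 4)
    )


class Conv4dLayer(Module):
    """Batched, trainable 4D convolution: (n,l,h,w,d,c) -> (n,l_out,h',w',d',c_out)."""

    def __init__(self, c_in: int, c_out: int, kl: int, spec: Conv4DSpec,
                 spatial=3, bias: bool = True,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        super().__init__()
        rng = rng or np.random.default_rng()
        kh, kw, kd = _as_triple(spatial)
        fan_in = kl * kh * kw * kd * c_in
        self.weight = Parameter(
            fan_in_uniform(rng, (kl, kh, kw, kd, c_in, c_out), fan_in, dtype)
        )
        self.bias = Parameter(np.zeros(c_out, dtype=dtype)) if bias else None
        self.spec = spec
        self.kl = kl
        self._pad = spec.resolved_padding((kh, kw, kd))

    def forward(self, x):
        n, l = x.shape[:2]
        st = self.spec.st
        l_out = temporal_out_len(l, self.kl, st)
        self._caches = []
        out = None
        for i in range(self.kl):
            # frames j*st+i for all output frames j, folded into the batch axis
            sub = x[:, i : i + st * l_out : st]
            flat = sub.reshape(n * l_out, *sub.shape[2:])
            y, cache = conv3d_forward(
                flat, self.weight.data[i], None, self.spec.spatial_stride, self._pad
            )
            self._caches.append(cache)
            out = y if out is None else out + y
        out = out.reshape(n, l_out, *out.shape[1:])
        if self.bias is not None:
            out = out + self.bias.data
        self._in_shape = x.shape
        self._l_out = l_out
        return out

    def backward(self, gout):
        n, l = self._in_shape[:2]
        st = self.spec.st
        l_out = self._l_out
        if self.bias is not None:
            self.bias.accumulate(gout.sum(axis=(0, 1, 2, 3, 4)))
        gflat = gout.reshape(n * l_out, *gout.shape[2:])
        gx = np.zeros(self._in_shape, dtype=gout.dtype)
        gw = np.zeros_like(self.weight.data)
        for i in range(self.kl):
            gxi, gwi, _ = conv3d_backward(gflat, self.weight.data[i], self._caches[i])
            gw[i] = gwi
            gx[:, i : i + st * l_out : st] += gxi.reshape(
                n, l_out, *gxi.shape[1:]
            )
        self.weight.accumulate(gw)
        return gx


class FlattenTime(Module):
    """Batched squeeze-and-flatten: (n,l,h,w,d,c) -> (n,h,w,d,l·c), time-major."""

    def forward(self, x):
        n, l, h, w, d, c = x.shape
        self._shape = x.shape
        return np.ascontiguousarray(x.transpose(0, 2, 3, 4, 1, 5)).reshape(
            n, h, w, d, l * c
        )

    def backward(self, gout):
        n, l, h, w, d, c = self._shape
        return np.ascontiguousarray(
            gout.reshape(n, h, w, d, l, c).transpose(0, 4, 1, 2, 3, 5)
        )
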