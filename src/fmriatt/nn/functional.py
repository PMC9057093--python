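"""Array-level primitives behind the layers (channels-last)."""

from __future__ import annotations

from itertools import product

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def _as_triple(v) -> tuple[int, int, int]:
    if np.isscalar(v):
        return (int(v),) * 3
    t = tuple(int(x) for x in v)
    if len(t) != 3:
        raise ValueError(f"expected 3 values, got {v!r}")
    return t


def conv3d_forward(
    x: np.ndarray,
    w: np.ndarray,
    b: np.ndarray | None,
    stride: int,
    padding,
) -> tuple[np.ndarray, tuple]:
    """Strided 3D cross-correlation.

    x: (n, h, w, d, c_in); w: (kh, kw, kd, c_in, c_out); returns (out, cache)
    with out (n, h', w', d', c_out).
    """
    ph, pw, pd = _as_triple(padding)
    kh, kw, kd, c_in, _ = w.shape
    if x.shape[4] != c_in:
        raise ValueError(
            f"channel mismatch: input has {x.shape[4]} channels, kernel expects {c_in}"
        )
    xp = np.pad(x, ((0, 0), (ph, ph), (pw, pw), (pd, pd), (0, 0)))
    if any(xp.shape[i + 1] < (kh, kw, kd)[i] for i in range(3)):
        raise ValueError(
            f"spatial extent {xp.shape[1:4]} smaller than kernel {(kh, kw, kd)}"
        )
    win = sliding_window_view(xp, (kh, kw, kd), axis=(1, 2, 3))
    win = win[:, ::stride, ::stride, ::stride]  # (n,h',w',d',c,kh,kw,kd)
    out = np.einsum("nhwdcijk,ijkco->nhwdo", win, w, optimize=True)
    if b is not None:
        out = out + b
    cache = (xp, stride, (ph, pw, pd), x.shape)
    return out, cache


def conv3d_backward(
    gout: np.ndarray, w: np.ndarray, cache: tuple
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Returns (gx, gw, gb)."""
    xp, stride, (ph, pw, pd), x_shape = cache
    kh, kw, kd = w.shape[:3]
    win = sliding_window_view(xp, (kh, kw, kd), axis=(1, 2, 3))
    win = win[:, ::stride, ::stride, ::stride]
    gw = np.einsum("nhwdcijk,nhwdo->ijkco", win, gout, optimize=True)
    gb = gout.sum(axis=(0, 1, 2, 3))
    gxp = np.zeros_like(xp)
    ho, wo, do = gout.shape[1:4]
    for i, j, k in product(range(kh), range(kw), range(kd)):
        g = np.einsum("nhwdo,co->nhwdc", gout, w[i, j, k], optimize=True)
        gxp[
            :,
            i : i + stride * ho : stride,
            j : j + stride * wo : stride,
            k : k + stride * do : stride,
        ] += g
    h, ww_, d = x_shape[1:4]
    gx = gxp[:, ph : ph + h, pw : pw + ww_, pd : pd + d]
    return gx, gw, gb


def conv3d_out_shape(spatial, kernel, stride: int, padding) -> tuple[int, int, int]:
    pad = _as_triple(padding)
    return tuple(
        (s + 2 * p - k) // stride + 1 for s, k, p in zip(spatial, kernel, pad)
    )


# -- linear interpolation resize ------------------------------------------


def _axis_weights(old: int, new: int):
    """Half-pixel-centre sampling positions (align_corners=False convention)."""
    pos = (np.arange(new) + 0.5) * (old / new) - 0.5
    pos = np.clip(pos, 0.0, old - 1.0)
    i0 = np.floor(pos).astype(np.intp)
    i1 = np.minimum(i0 + 1, old - 1)
    w1 = pos - i0
    return i0, i1, w1


def resize_linear(x: np.ndarray, target, axes=(1, 2, 3)) -> np.ndarray:
    """Separable linear resize of `x` along `axes` to sizes `target`."""
    out = x
    for ax, new in zip(axes, target):
        old = out.shape[ax]
        if old == new:
            continue
        i0, i1, w1 = _axis_weights(old, new)
        a = np.moveaxis(out, ax, 0)
        dtype = out.dtype if np.issubdtype(out.dtype, np.floating) else np.float64
        shp = (len(w1),) + (1,) * (a.ndim - 1)
        a = a[i0] * (1.0 - w1.astype(dtype)).reshape(shp) + a[i1] * w1.astype(
            dtype
        ).reshape(shp)
        out = np.moveaxis(a, 0, ax)
    return out


def resize_linear_backward(gout: np.ndarray, source_shape, axes=(1, 2, 3)) -> np.ndarray:
    """Adjoint of :func:`resize_linear` (axes processed in reverse)."""
    gx = gout
    for ax in reversed(list(axes)):
        old = source_shape[ax]
        new = gx.shape[ax]
        if old == new:
            continue
        i0, i1, w1 = _axis_weights(old, new)
        g = np.moveaxis(gx, ax, 0)
        acc = np.zeros((old,) + g.shape[1:], dtype=g.dtype)
        shp = (len(w1),) + (1,) * (g.ndim - 1)
        np.add.at(acc, i0, g * (1.0 - w1).reshape(shp))
        np.add.at(acc, i1, g * w1.reshape(shp))
        gx = np.moveaxis(acc, 0, ax)
    return gx
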