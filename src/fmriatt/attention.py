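"""3D mixed residual-attention module.

Each stage splits into a main branch M(x) — a pre-activation ResNet block —
and a U-shaped attention branch: `depth_steps` stacks of (2x2x2 max-pool +
ResBlock) down, the mirrored count of (trilinear upsample + ResBlock) up, a
1x1x1 convolution to match M's channel width, and a sigmoid, giving a mask
A(x) with every element in (0, 1).  Attention residual learning combines the
branches as ``out = M(x) · (1 + A(x))`` so the mask re-weights features
without ever destroying them: the A→0 limit is the identity on M(x) and the
output is bounded by [|M|, 2|M|] elementwise.

When the main branch strides (main_stride=2) the attention branch reaches
M's grid by leaving its first down-step uncompensated (one fewer up-step),
keeping the two branch depths symmetric.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn.core import Module, ModuleList
from .nn.layers import BatchNorm, Conv3d, MaxPool3d, ReLU, Sigmoid, Upsample3d


class ConfigurationError(ValueError):
    pass


@dataclass
class ResBlockSpec:
    c_in: int
    c_out: int
    stride: int = 1
    normalize: bool = True

    def __post_init__(self):
        if self.stride not in (1, 2):
            raise ConfigurationError("ResBlock stride must be 1 or 2")


@dataclass
class AttentionModuleSpec:
    c_in: int
    c_out: int
    depth_steps: int = 2
    main_stride: int = 1

    def __post_init__(self):
        if self.depth_steps < 0:
            raise ConfigurationError("depth_steps must be >= 0")
        if self.main_stride not in (1, 2):
            raise ConfigurationError("main_stride must be 1 or 2")
        if self.main_stride == 2 and self.depth_steps < 1:
            raise ConfigurationError(
                "a strided attention module needs depth_steps >= 1 (the first "
                "down-step realizes the stride)"
            )


class ResBlock(Module):
    """Pre-activation residual block: BN-ReLU-Conv(stride)-BN-ReLU-Conv + shortcut.

    The shortcut is the identity when geometry permits, else a strided 1x1x1
    projection.  With normalization disabled and zero convolution weights the
    block is exactly the identity map.
    """

    def __init__(self, spec: ResBlockSpec, rng: np.random.Generator | None = None,
                 dtype=np.float32):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.spec = spec
        self.norm1 = BatchNorm(spec.c_in, dtype=dtype) if spec.normalize else None
        self.act1 = ReLU()
        self.conv1 = Conv3d(spec.c_in, spec.c_out, 3, stride=spec.stride,
                            rng=rng, dtype=dtype)
        self.norm2 = BatchNorm(spec.c_out, dtype=dtype) if spec.normalize else None
        self.act2 = ReLU()
        self.conv2 = Conv3d(spec.c_out, spec.c_out, 3, stride=1, rng=rng, dtype=dtype)
        if spec.c_in != spec.c_out or spec.stride != 1:
            self.proj = Conv3d(spec.c_in, spec.c_out, 1, stride=spec.stride,
                               padding=(0, 0, 0), rng=rng, dtype=dtype)
        else:
            self.proj = None

    def forward(self, x):
        if x.shape[-1] != self.spec.c_in:
            raise ValueError(
                f"ResBlock expects {self.spec.c_in} channels, got {x.shape[-1]}"
            )
        h = x
        if self.norm1 is not None:
            h = self.norm1(h)
        h = self.act1(h)
        h = self.conv1(h)
        if self.norm2 is not None:
            h = self.norm2(h)
        h = self.act2(h)
        h = self.conv2(h)
        s = self.proj(x) if self.proj is not None else x
        return h + s

    def backward(self, gout):
        g = self.conv2.backward(gout)
        g = self.act2.backward(g)
        if self.norm2 is not None:
            g = self.norm2.backward(g)
        g = self.conv1.backward(g)
        g = self.act1.backward(g)
        if self.norm1 is not None:
            g = self.norm1.backward(g)
        gs = self.proj.backward(gout) if self.proj is not None else gout
        return g + gs


class AttentionBranch(Module):
    """U-shaped mask branch ending in a 1x1x1 projection and a sigmoid."""

    def __init__(self, spec: AttentionModuleSpec,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.spec = spec
        c = spec.c_in
        self.pools = ModuleList([MaxPool3d() for _ in range(spec.depth_steps)])
        self.down_blocks = ModuleList(
            [ResBlock(ResBlockSpec(c, c), rng=rng, dtype=dtype)
             for _ in range(spec.depth_steps)]
        )
        self.n_up = spec.depth_steps - (1 if spec.main_stride == 2 else 0)
        self.ups = ModuleList([Upsample3d((1, 1, 1)) for _ in range(self.n_up)])
        self.up_blocks = ModuleList(
            [ResBlock(ResBlockSpec(c, c), rng=rng, dtype=dtype)
             for _ in range(self.n_up)]
        )
        self.out_conv = Conv3d(c, spec.c_out, 1, stride=1, padding=(0, 0, 0),
                               rng=rng, dtype=dtype)
        self.sigmoid = Sigmoid()

    def forward(self, x):
        if min(x.shape[1:4]) < 2 ** self.spec.depth_steps:
            raise ConfigurationError(
                f"spatial extent {x.shape[1:4]} collapses inside a U-branch of "
                f"{self.spec.depth_steps} down-steps"
            )
        shapes = []
        h = x
        for pool, rb in zip(self.pools, self.down_blocks):
            shapes.append(h.shape[1:4])
            h = rb(pool(h))
        for i, (up, rb) in enumerate(zip(self.ups, self.up_blocks)):
            up.target_shape = tuple(shapes[len(shapes) - 1 - i])
            h = rb(up(h))
        return self.sigmoid(self.out_conv(h))

    def backward(self, gout):
        g = self.sigmoid.backward(gout)
        g = self.out_conv.backward(g)
        for up, rb in zip(reversed(list(self.ups)), reversed(list(self.up_blocks))):
            g = up.backward(rb.backward(g))
        for pool, rb in zip(reversed(list(self.pools)),
                            reversed(list(self.down_blocks))):
            g = pool.backward(rb.backward(g))
        return g


def attention_combine(m: np.ndarray, a: np.ndarray) -> np.ndarray:
    """Attention residual learning: elementwise ``m · (1 + a)``."""
    if m.shape != a.shape:
        raise ValueError(f"shape mismatch: M {m.shape} vs A {a.shape}")
    return m * (1.0 + a)


class AttentionModule(Module):
    """Full stage: returns (combined output, attention mask)."""

    def __init__(self, spec: AttentionModuleSpec,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.spec = spec
        self.main = ResBlock(
            ResBlockSpec(spec.c_in, spec.c_out, stride=spec.main_stride),
            rng=rng, dtype=dtype,
        )
        self.branch = AttentionBranch(spec, rng=rng, dtype=dtype)

    def forward(self, x):
        m = self.main(x)
        a = self.branch(x)
        if m.shape != a.shape:
            raise ConfigurationError(
                f"branch outputs disagree: M {m.shape} vs A {a.shape}"
            )
        self._m, self._a = m, a
        return attention_combine(m, a), a

    def backward(self, gout):
        gm = gout * (1.0 + self._a)
        ga = gout * self._m
        return self.main.backward(gm) + self.branch.backward(ga)
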