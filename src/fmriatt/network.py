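"""Decoder assembly: 4D front end, four 3D attention stages, pooled head.

Three variants are built from one config:

- ``conv4d_attention`` — strided 4D convolution front end, temporal
  squeeze-and-flatten, four mixed residual-attention stages, global average
  pooling, and a fully-connected head (the primary model);
- ``conv4d_plain`` — same front end and channel plan, but each stage is the
  attention module's main branch alone (no mask);
- ``conv3d_attention`` — the front end degenerates to a shared per-frame 3D
  convolution (temporal kernel length 1, stride 1) whose frame outputs are
  flattened to channels, the classic frames-as-channels 3D baseline.

Per-stage strides and U-branch depths are configurable; depths are clamped
so the attention U never pools a grid below one voxel.  Classification heads
emit one score per class; regression heads a single real per instance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import floor, log2

import numpy as np

from .attention import (
    AttentionModule,
    AttentionModuleSpec,
    ConfigurationError,
    ResBlock,
    ResBlockSpec,
)
from .conv4d import Conv4DSpec, Conv4dLayer, FlattenTime, temporal_out_len
from .nn.core import Module, ModuleList
from .nn.layers import GlobalAvgPool, Linear

VARIANTS = ("conv4d_attention", "conv4d_plain", "conv3d_attention")


@dataclass
class ModelConfig:
    variant: str = "conv4d_attention"
    kl: int = 3
    st: int = 2
    stage_channels: tuple = (16, 16, 32, 32)
    n_classes: int = 3
    head: str = "classify"
    seed: int = 0
    input_grid: tuple = (16, 16, 16)
    seg_len: int = 8
    conv4d_channels: int = 8
    spatial_kernel: int = 3
    spatial_stride: int = 2
    stage_strides: tuple = (1, 2, 1, 1)
    depth_steps: tuple = (2, 2, 1, 1)

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ConfigurationError(
                f"unknown variant {self.variant!r}; expected one of {VARIANTS}"
            )
        if len(self.stage_channels) != 4:
            raise ConfigurationError("stage_channels must list four stages")
        if self.head not in ("classify", "regress"):
            raise ConfigurationError("head must be 'classify' or 'regress'")
        if self.head == "classify" and self.n_classes < 2:
            raise ConfigurationError("classification needs n_classes >= 2")
        if len(self.stage_strides) != 4 or len(self.depth_steps) != 4:
            raise ConfigurationError("stage_strides/depth_steps must have length 4")

    @property
    def effective_kl(self) -> int:
        return 1 if self.variant == "conv3d_attention" else self.kl

    @property
    def effective_st(self) -> int:
        return 1 if self.variant == "conv3d_attention" else self.st

    @property
    def l_out(self) -> int:
        return temporal_out_len(self.seg_len, self.effective_kl, self.effective_st)

    def to_dict(self) -> dict:
        return {
            "variant": self.variant, "kl": self.kl, "st": self.st,
            "stage_channels": list(self.stage_channels),
            "n_classes": self.n_classes, "head": self.head, "seed": self.seed,
            "input_grid": list(self.input_grid), "seg_len": self.seg_len,
            "conv4d_channels": self.conv4d_channels,
            "spatial_kernel": self.spatial_kernel,
            "spatial_stride": self.spatial_stride,
            "stage_strides": list(self.stage_strides),
            "depth_steps": list(self.depth_steps),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        for key in ("stage_channels", "input_grid", "stage_strides", "depth_steps"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class ModelOutput:
    """scores: (n, n_classes) for classification, (n,) for regression;
    masks: per-stage attention masks (n,h,w,d,c), low-level first."""

    scores: np.ndarray
    masks: list = field(default_factory=list)


def _ceil_div(a: int, s: int) -> int:
    return -(-a // s)


def plan_grids(cfg: ModelConfig) -> list[tuple[int, int, int]]:
    """Spatial grid entering each stage (index 0..3) plus the final grid."""
    g = tuple(_ceil_div(a, cfg.spatial_stride) for a in cfg.input_grid)
    grids = [g]
    for s in cfg.stage_strides:
        g = tuple(_ceil_div(a, s) for a in g)
        grids.append(g)
    return grids


class Model(Module):
    def __init__(self, cfg: ModelConfig):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        spec = Conv4DSpec(st=cfg.effective_st, spatial_stride=cfg.spatial_stride)
        self.front = Conv4dLayer(
            1, cfg.conv4d_channels, cfg.effective_kl, spec,
            spatial=cfg.spatial_kernel, rng=rng,
        )
        self.flatten = FlattenTime()
        grids = plan_grids(cfg)
        self.stage_depths = []
        stages = []
        c_in = cfg.l_out * cfg.conv4d_channels
        for i, c_out in enumerate(cfg.stage_channels):
            stride = cfg.stage_strides[i]
            max_depth = floor(log2(min(grids[i]))) if min(grids[i]) > 1 else 0
            depth = min(cfg.depth_steps[i], max_depth)
            if stride == 2 and depth < 1:
                raise ConfigurationError(
                    f"stage {i}: grid {grids[i]} cannot support a strided "
                    "attention module"
                )
            self.stage_depths.append(depth)
            if cfg.variant in ("conv4d_attention", "conv3d_attention"):
                stages.append(AttentionModule(
                    AttentionModuleSpec(c_in, c_out, depth_steps=depth,
                                        main_stride=stride),
                    rng=rng,
                ))
            else:
                stages.append(ResBlock(
                    ResBlockSpec(c_in, c_out, stride=stride), rng=rng,
                ))
            c_in = c_out
        self.stages = ModuleList(stages)
        self.pool = GlobalAvgPool()
        n_out = cfg.n_classes if cfg.head == "classify" else 1
        self.fc = Linear(cfg.stage_channels[-1], n_out, rng=rng)

    @property
    def has_attention(self) -> bool:
        return self.cfg.variant != "conv4d_plain"

    def forward(self, x: np.ndarray) -> ModelOutput:
        if x.ndim != 6 or x.shape[-1] != 1:
            raise ValueError(
                "model input must be (batch, frames, h, w, d, 1); got "
                f"shape {x.shape}"
            )
        if temporal_out_len(x.shape[1], self.cfg.effective_kl,
                            self.cfg.effective_st) != self.cfg.l_out:
            raise ValueError(
                f"4D front end: {x.shape[1]} input frames are incompatible with "
                f"the configured segment length {self.cfg.seg_len}"
            )
        h = self.flatten(self.front(x))
        masks = []
        for stage in self.stages:
            out = stage(h)
            if isinstance(out, tuple):
                h, a = out
                masks.append(a)
            else:
                h = out
        scores = self.fc(self.pool(h))
        if self.cfg.head == "regress":
            scores = scores[:, 0]
        return ModelOutput(scores=scores, masks=masks)

    def backward(self, gscores: np.ndarray) -> np.ndarray:
        if self.cfg.head == "regress" and gscores.ndim == 1:
            gscores = gscores[:, None]
        g = self.pool.backward(self.fc.backward(gscores))
        for stage in reversed(list(self.stages)):
            g = stage.backward(g)
        return self.front.backward(self.flatten.backward(g))

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())


def build_model(cfg: ModelConfig) -> Model:
    """Construct a model variant; identical configs yield identical weights."""
    return Model(cfg)
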