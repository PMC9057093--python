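"""Attention-mask extraction, aggregation, contrasts, and export.

For an attention-variant decoder, every stage exposes its sigmoid mask
A(x).  Masks are collected per condition by averaging over every stride-1
temporal window of every instance of that condition, plus an unweighted
"average" across conditions.  Condition-minus-average contrasts are signed
volumes (they sum to zero across conditions by construction); the class-c
contrast concentrating inside class-c's activation ROI is the testable form
of "high-level masks cover task-specific areas".

Masks live on the stage's feature grid; each carries an affine composed
from the input affine and the cumulative downsampling, so they can be
resampled onto the input voxel grid (or any anatomical volume sharing the
input's world space) with trilinear interpolation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .network import Model
from .nn.functional import resize_linear
from .training import standardize

AVERAGE = "average"


class UnsupportedModelError(TypeError):
    pass


@dataclass
class AttentionMask:
    stage: int
    channel: int | None          # None = channel-mean volume
    condition: object            # class label or "average"
    data: np.ndarray             # 3D, feature-grid coordinates
    affine: np.ndarray           # voxel-to-world of the feature grid
    contrast: bool = False


@dataclass
class MaskBundle:
    masks: dict                  # (stage, condition) -> (h, w, d, c) mean mask
    sample_counts: dict          # condition -> number of averaged windows
    affines: list                # per-stage feature-grid affine
    conditions: list             # class labels (without "average")
    input_grid: tuple
    input_affine: np.ndarray

    @property
    def n_stages(self) -> int:
        return len(self.affines)

    def n_channels(self, stage: int) -> int:
        return self.masks[(stage, AVERAGE)].shape[-1]

    def get(self, stage: int, channel: int | None, condition) -> AttentionMask:
        if (stage, condition) not in self.masks:
            raise KeyError(f"no mask for stage {stage}, condition {condition!r}")
        m = self.masks[(stage, condition)]
        data = m[..., channel] if channel is not None else m.mean(axis=-1)
        return AttentionMask(stage=stage, channel=channel, condition=condition,
                             data=np.asarray(data), affine=self.affines[stage])


def _stage_affine(input_affine: np.ndarray, input_grid, feat_grid) -> np.ndarray:
    """Affine of a feature grid whose voxel i covers input voxels
    [i*f, (i+1)*f): scale by f, shift to the block centre."""
    f = np.array(input_grid, dtype=float) / np.array(feat_grid, dtype=float)
    t = np.eye(4)
    t[:3, :3] = np.diag(f)
    t[:3, 3] = (f - 1.0) / 2.0
    return np.asarray(input_affine, dtype=float) @ t


def collect_masks(model: Model, instances, k: int,
                  input_affine: np.ndarray | None = None) -> MaskBundle:
    """Average per-stage masks per condition over all instances' stride-1
    windows; add the unweighted across-condition "average"."""
    if not model.has_attention:
        raise UnsupportedModelError(
            f"variant {model.cfg.variant!r} has no attention masks"
        )
    model.eval()
    sums: dict[tuple, np.ndarray] = {}
    counts: dict[object, int] = {}
    input_grid = instances[0].grid
    for inst in instances:
        windows = np.stack([
            standardize(inst.series[s : s + k, ..., None])
            for s in range(inst.n_frames - k + 1)
        ])
        out = model.forward(windows)
        c = inst.class_label
        counts[c] = counts.get(c, 0) + windows.shape[0]
        for stage, mask in enumerate(out.masks):
            key = (stage, c)
            agg = mask.sum(axis=0, dtype=np.float64)
            sums[key] = sums.get(key, 0.0) + agg
    conditions = sorted(counts)
    masks = {}
    n_stages = len({s for s, _ in sums})
    for stage in range(n_stages):
        per_cond = []
        for c in conditions:
            m = sums[(stage, c)] / counts[c]
            masks[(stage, c)] = m
            per_cond.append(m)
        masks[(stage, AVERAGE)] = np.mean(per_cond, axis=0)
    if input_affine is None:
        input_affine = np.eye(4)
    affines = [
        _stage_affine(input_affine, input_grid, masks[(s, AVERAGE)].shape[:3])
        for s in range(n_stages)
    ]
    counts[AVERAGE] = int(sum(counts.values()))
    return MaskBundle(masks=masks, sample_counts=counts, affines=affines,
                      conditions=conditions, input_grid=tuple(input_grid),
                      input_affine=np.asarray(input_affine, dtype=float))


def contrast_mask(bundle: MaskBundle, stage: int, channel: int | None,
                  condition) -> AttentionMask:
    """Signed condition-minus-average contrast."""
    cond = bundle.get(stage, channel, condition)
    avg = bundle.get(stage, channel, AVERAGE)
    return AttentionMask(stage=stage, channel=channel, condition=condition,
                         data=cond.data - avg.data, affine=cond.affine,
                         contrast=True)


def upsample_to_input(mask: AttentionMask, target_grid,
                      target_affine: np.ndarray) -> AttentionMask:
    """Trilinear resampling of a feature-grid mask onto a voxel grid sharing
    its world space."""
    target_affine = np.asarray(target_affine, dtype=float)
    if abs(np.linalg.det(target_affine)) < 1e-12:
        raise ValueError("target affine is singular")
    data = resize_linear(mask.data[None, ..., None], tuple(target_grid))[0, ..., 0]
    return AttentionMask(stage=mask.stage, channel=mask.channel,
                         condition=mask.condition, data=data,
                         affine=target_affine, contrast=mask.contrast)


def rank_channels(bundle: MaskBundle, stage: int) -> list[int]:
    """Channels ordered by decreasing variance of the condition contrast —
    an objective default for which channels to display."""
    stack = np.stack([
        bundle.masks[(stage, c)] - bundle.masks[(stage, AVERAGE)]
        for c in bundle.conditions
    ])  # (cond, h, w, d, ch)
    var = stack.var(axis=0).mean(axis=(0, 1, 2))
    return list(np.argsort(var)[::-1])


def roi_contrast_statistic(bundle: MaskBundle, class_rois,
                           stage: int | None = None) -> dict[int, float]:
    """Per class c: mean(upsampled channel-mean contrast inside ROI_c) minus
    its mean inside the other classes' ROIs."""
    if stage is None:
        stage = bundle.n_stages - 1
    stats = {}
    for c in bundle.conditions:
        cm = contrast_mask(bundle, stage, None, c)
        up = upsample_to_input(cm, bundle.input_grid, bundle.input_affine)
        own = float(up.data[class_rois[c]].mean())
        others = np.zeros(bundle.input_grid, dtype=bool)
        for j, roi in enumerate(class_rois):
            if j != c:
                others |= roi
        stats[c] = own - float(up.data[others].mean())
    return stats


def export_masks(bundle: MaskBundle, out_dir, cmap: str = "RdBu_r") -> list[str]:
    """Write every (stage, channel, condition) mask and contrast as NIfTI,
    plus a per-stage orthogonal-slice overview figure; returns the manifest
    (also saved as manifest.json)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import nibabel as nib

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = []

    def _save(vol: AttentionMask, name: str):
        path = out / name
        nib.save(nib.Nifti1Image(np.asarray(vol.data, dtype=np.float32),
                                 vol.affine), path)
        manifest.append(str(path))

    for stage in range(bundle.n_stages):
        for ch in range(bundle.n_channels(stage)):
            for cond in bundle.conditions + [AVERAGE]:
                _save(bundle.get(stage, ch, cond),
                      f"mask_stage-{stage}_ch-{ch}_cond-{cond}.nii.gz")
            for cond in bundle.conditions:
                _save(contrast_mask(bundle, stage, ch, cond),
                      f"contrast_stage-{stage}_ch-{ch}_cond-{cond}.nii.gz")
        # overview: channel-mean raw mask and per-condition contrasts
        n_cond = len(bundle.conditions)
        fig, axes = plt.subplots(n_cond + 1, 3, figsize=(9, 3 * (n_cond + 1)))
        axes = np.atleast_2d(axes)
        raw = bundle.get(stage, None, AVERAGE).data
        _ortho(axes[0], raw, vcenter=0.5, cmap=cmap,
               title=f"stage {stage} mean mask")
        for r, cond in enumerate(bundle.conditions, start=1):
            con = contrast_mask(bundle, stage, None, cond).data
            _ortho(axes[r], con, vcenter=0.0, cmap=cmap,
                   title=f"contrast class {cond}")
        fig.tight_layout()
        fig_path = out / f"overview_stage-{stage}.png"
        fig.savefig(fig_path, dpi=100)
        plt.close(fig)
        manifest.append(str(fig_path))
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


def _ortho(ax_row, vol: np.ndarray, vcenter: float, cmap: str, title: str):
    half = max(abs(float(vol.min()) - vcenter), abs(float(vol.max()) - vcenter))
    half = half or 1e-6
    mids = [s // 2 for s in vol.shape]
    planes = [vol[mids[0], :, :], vol[:, mids[1], :], vol[:, :, mids[2]]]
    for ax, plane in zip(ax_row, planes):
        ax.imshow(plane.T, origin="lower", cmap=cmap,
                  vmin=vcenter - half, vmax=vcenter + half)
        ax.set_axis_off()
    ax_row[0].set_title(title, fontsize=8, loc="left")
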