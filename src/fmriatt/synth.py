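"""Synthetic 4D fMRI generator.

Emulates the statistical structure a task-fMRI decoder assumes, at desk
scale: a boxcar task design convolved with the canonical double-gamma
hemodynamic response, painted on disjoint per-class activation ROIs inside
an ellipsoidal brain mask, on a baseline of 100 signal units with i.i.d.
Gaussian voxel noise.  Subject-level trait scores modulate activation
amplitude linearly (``amplitude + trait_slope · trait``), giving transfer
workflows a recoverable regression target.

Two designs are supported: ``block`` (one boxcar of ``block_frames`` frames
starting at frame 0) and ``event`` (a single 1-frame stimulus after 2 lead-in
frames, optionally onset-jittered), the reduced-scale analogues of a
block-design cognitive battery and an event-related picture-viewing
paradigm.

Simplifications, deliberate: noise is white in space and time (no drift,
motion, or spatial autocorrelation), and every instance of a class shares
one ROI.  What passes on this generator therefore demonstrates mechanism,
not field performance.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import gamma as gamma_dist

from .types import TaskInstance

BASELINE = 100.0  # arbitrary units, typical normalized BOLD scale


class ConfigurationError(ValueError):
    pass


@dataclass
class SynthConfig:
    grid_shape: tuple = (16, 16, 16)
    n_frames: int = 12
    tr: float = 1.0
    n_classes: int = 3
    n_subjects: int = 12
    instances_per_subject_per_class: int = 2
    amplitude: float = 2.0
    noise_sd: float = 2.0
    trait_slope: float = 0.5
    block_frames: int = 8
    seed: int = 0
    design: str = "block"  # "block" or "event"
    onset_jitter: bool = False

    def __post_init__(self):
        self.grid_shape = tuple(int(g) for g in self.grid_shape)
        if len(self.grid_shape) != 3 or any(g < 8 for g in self.grid_shape):
            raise ConfigurationError("grid_shape needs three extents, each >= 8")
        if self.n_frames < self.block_frames:
            raise ConfigurationError("n_frames must be >= block_frames")
        if self.block_frames < 1 or self.n_frames < 1:
            raise ConfigurationError("frame counts must be positive")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if self.n_classes < 2:
            raise ConfigurationError("need at least 2 classes")
        if self.n_subjects < 1 or self.instances_per_subject_per_class < 1:
            raise ConfigurationError("subject/instance counts must be positive")
        if self.tr <= 0:
            raise ConfigurationError("tr must be positive")
        if self.design not in ("block", "event"):
            raise ConfigurationError("design must be 'block' or 'event'")


@dataclass
class GroundTruth:
    class_rois: list          # per-class boolean 3D masks
    brain_mask: np.ndarray    # boolean 3D mask
    hrf: np.ndarray           # sampled double-gamma response
    regressor: np.ndarray = field(default=None)  # design ⊛ hrf, length n_frames


def canonical_hrf(tr: float, duration: float = 32.0) -> np.ndarray:
    """Double-gamma hemodynamic response sampled every `tr` seconds.

    SPM-convention parameters: response delay 6 s, undershoot delay 16 s,
    dispersions 1, undershoot ratio 1/6; normalized to unit peak.  Length is
    ``floor(duration/tr) + 1`` samples.
    """
    if tr <= 0:
        raise ValueError("tr must be positive")
    if duration < 2 * tr:
        raise ValueError("duration must cover at least two samples")
    t = np.arange(int(np.floor(duration / tr)) + 1) * tr
    h = gamma_dist.pdf(t, 6.0, scale=1.0) - gamma_dist.pdf(t, 16.0, scale=1.0) / 6.0
    return h / h.max()


def trait_assignments(n_subjects: int, seed: int) -> dict[str, float]:
    """One standard-normal trait draw per subject, deterministic in the seed."""
    if n_subjects < 2:
        raise ConfigurationError("need at least 2 subjects for trait assignment")
    rng = np.random.default_rng(seed)
    draws = rng.standard_normal(n_subjects)
    return {f"sub-{i:03d}": float(draws[i]) for i in range(n_subjects)}


def _ellipsoid(grid, center, semi_axes) -> np.ndarray:
    idx = np.indices(grid, dtype=float)
    d2 = sum(
        ((idx[a] - center[a]) / semi_axes[a]) ** 2 for a in range(3)
    )
    return d2 <= 1.0


def make_rois(grid, n_classes: int) -> tuple[list[np.ndarray], np.ndarray]:
    """Brain mask (centered ellipsoid) and disjoint per-class ellipsoidal ROIs
    placed on a ring in the central axial plane."""
    center = tuple((g - 1) / 2.0 for g in grid)
    brain = _ellipsoid(grid, center, tuple(0.45 * g for g in grid))
    roi_r = max(2.0, min(grid) / 8.0)
    ring = 0.6 * 0.45 * min(grid)
    rois = []
    for c in range(n_classes):
        theta = 2 * np.pi * c / n_classes + np.pi / 4
        cc = (
            center[0] + ring * np.cos(theta),
            center[1] + ring * np.sin(theta),
            center[2],
        )
        roi = _ellipsoid(grid, cc, (roi_r, roi_r, roi_r)) & brain
        rois.append(roi)
    for i in range(n_classes):
        if not rois[i].any():
            raise ConfigurationError(f"class ROI {i} is empty on grid {grid}")
        for j in range(i):
            if (rois[i] & rois[j]).any():
                raise ConfigurationError(
                    f"class ROIs {j} and {i} overlap on grid {grid}; "
                    "use a larger grid or fewer classes"
                )
    return rois, brain


def task_regressor(cfg: SynthConfig, hrf: np.ndarray, onset: int = 0) -> np.ndarray:
    """Boxcar (block) or single-frame event convolved with the HRF, truncated
    to the series length."""
    box = np.zeros(cfg.n_frames)
    if cfg.design == "block":
        box[onset : onset + cfg.block_frames] = 1.0
    else:
        box[min(onset, cfg.n_frames - 1)] = 1.0
    return np.convolve(box, hrf)[: cfg.n_frames]


def generate_dataset(cfg: SynthConfig) -> tuple[list[TaskInstance], GroundTruth]:
    """Full synthetic dataset: n_subjects x n_classes x instances each."""
    rng = np.random.default_rng(cfg.seed)
    rois, brain = make_rois(cfg.grid_shape, cfg.n_classes)
    hrf = canonical_hrf(cfg.tr, duration=32.0)
    traits = trait_assignments(max(cfg.n_subjects, 2), seed=cfg.seed + 1)
    base_reg = task_regressor(cfg, hrf, onset=0 if cfg.design == "block" else 2)
    instances = []
    for s in range(cfg.n_subjects):
        sid = f"sub-{s:03d}"
        trait = traits[sid]
        for c in range(cfg.n_classes):
            for _ in range(cfg.instances_per_subject_per_class):
                if cfg.design == "event" and cfg.onset_jitter:
                    onset = 2 + int(rng.integers(0, 2))
                    reg = task_regressor(cfg, hrf, onset=onset)
                else:
                    reg = base_reg
                series = np.zeros((cfg.n_frames,) + cfg.grid_shape, dtype=np.float32)
                series[:, brain] = BASELINE
                gain = cfg.amplitude + cfg.trait_slope * trait
                series[:, rois[c]] += (gain * reg)[:, None].astype(np.float32)
                if cfg.noise_sd > 0:
                    noise = rng.normal(
                        0.0, cfg.noise_sd, size=(cfg.n_frames, int(brain.sum()))
                    )
                    series[:, brain] += noise.astype(np.float32)
                instances.append(
                    TaskInstance(sid, c, trait, series, tr=cfg.tr)
                )
    truth = GroundTruth(class_rois=rois, brain_mask=brain, hrf=hrf,
                        regressor=base_reg)
    return instances, truth


# -- on-disk form ----------------------------------------------------------


def write_dataset(instances: list[TaskInstance], truth: GroundTruth,
                  out_dir, affine: np.ndarray | None = None) -> Path:
    """Write instances as 4D NIfTI files plus a labels TSV; ROI masks as 3D
    NIfTI.  Returns the labels-table path."""
    import nibabel as nib

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if affine is None:
        affine = np.eye(4)
    rows = []
    for i, inst in enumerate(instances):
        fname = f"inst-{i:05d}_{inst.subject_id}_class-{inst.class_label}.nii.gz"
        data = np.moveaxis(inst.series, 0, -1)  # (x,y,z,t) on disk
        img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine)
        img.header.set_zooms(img.header.get_zooms()[:3] + (inst.tr,))
        img.header.set_xyzt_units("mm", "sec")
        nib.save(img, out / fname)
        rows.append((inst.subject_id, inst.class_label, inst.trait, fname))
    for c, roi in enumerate(truth.class_rois):
        nib.save(nib.Nifti1Image(roi.astype(np.uint8), affine),
                 out / f"roi_class-{c}.nii.gz")
    nib.save(nib.Nifti1Image(truth.brain_mask.astype(np.uint8), affine),
             out / "brain_mask.nii.gz")
    table = out / "labels.tsv"
    with open(table, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["subject_id", "class_label", "trait", "filename"])
        w.writerows(rows)
    return table
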