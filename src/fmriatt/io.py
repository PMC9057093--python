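"""NIfTI reading, fixed-box cropping, and labelled-dataset assembly.

Series are stored (t, x, y, z) in memory and (x, y, z, t) on disk; the
conversion happens only at this boundary.  Voxel indices are 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .types import TaskInstance, VolumeSeries


class FormatError(ValueError):
    pass


class DegenerateInputError(ValueError):
    pass


@dataclass
class CropSpec:
    """Fixed spatial bounding box; the field-standard whole-brain box is
    (80, 96, 88) voxels in 2 mm MNI space."""

    target_shape: tuple = (80, 96, 88)

    def __post_init__(self):
        self.target_shape = tuple(int(s) for s in self.target_shape)
        if len(self.target_shape) != 3 or any(s < 1 for s in self.target_shape):
            raise ValueError("target_shape needs three positive extents")


def load_series(path) -> VolumeSeries:
    """Load a 3D/4D NIfTI file; 3D volumes are promoted to a single frame."""
    path = Path(path)
    try:
        img = nib.load(path)
        data = np.asarray(img.get_fdata(dtype=np.float32))
    except Exception as e:  # noqa: BLE001 - re-raise with the offending path
        raise FormatError(f"cannot read NIfTI file {path}: {e}") from e
    if data.ndim == 3:
        data = data[..., None]
    if data.ndim != 4:
        raise FormatError(
            f"{path}: unsupported dimensionality {data.ndim}; expected 3 or 4"
        )
    zooms = img.header.get_zooms()
    tr = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 1.0
    return VolumeSeries(
        data=np.moveaxis(data, -1, 0), affine=np.asarray(img.affine), tr=tr
    )


def save_series(series: VolumeSeries, path) -> None:
    data = np.moveaxis(series.data, 0, -1).astype(np.float32)
    img = nib.Nifti1Image(data, series.affine)
    img.header.set_zooms(img.header.get_zooms()[:3] + (series.tr,))
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))


def crop_to_box(series: VolumeSeries, spec: CropSpec) -> VolumeSeries:
    """Crop/pad the brain-content bounding box to a fixed spatial shape.

    Brain content is taken as voxels whose temporal mean exceeds 0; the
    content box is centered in the target window and padded symmetrically
    with zeros where the source runs out.  The affine is translated so every
    retained voxel keeps its world coordinates, which also makes the
    operation idempotent.
    """
    mean = series.data.mean(axis=0)
    nz = np.nonzero(mean > 0)
    if nz[0].size == 0:
        raise DegenerateInputError("empty brain mask: no voxel has positive mean")
    starts = []
    for ax in range(3):
        lo, hi = int(nz[ax].min()), int(nz[ax].max()) + 1
        ctr = (lo + hi) // 2
        starts.append(ctr - spec.target_shape[ax] // 2)
    t = series.data.shape[0]
    out = np.zeros((t,) + spec.target_shape, dtype=series.data.dtype)
    src_lo = [max(0, s) for s in starts]
    src_hi = [
        min(series.data.shape[ax + 1], starts[ax] + spec.target_shape[ax])
        for ax in range(3)
    ]
    dst_lo = [src_lo[ax] - starts[ax] for ax in range(3)]
    dst_hi = [dst_lo[ax] + (src_hi[ax] - src_lo[ax]) for ax in range(3)]
    out[
        :,
        dst_lo[0] : dst_hi[0],
        dst_lo[1] : dst_hi[1],
        dst_lo[2] : dst_hi[2],
    ] = series.data[
        :,
        src_lo[0] : src_hi[0],
        src_lo[1] : src_hi[1],
        src_lo[2] : src_hi[2],
    ]
    affine = series.affine.copy()
    affine[:3, 3] = affine[:3, 3] + affine[:3, :3] @ np.asarray(starts, dtype=float)
    return VolumeSeries(data=out, affine=affine, tr=series.tr)


def load_dataset(table, root=None) -> list[TaskInstance]:
    """Assemble labelled instances from a labels TSV
    (subject_id, class_label, trait, filename)."""
    table = Path(table)
    root = Path(root) if root is not None else table.parent
    df = pd.read_csv(table, sep="\t")
    required = {"subject_id", "class_label", "trait", "filename"}
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise FormatError(f"{table}: missing columns {sorted(missing_cols)}")
    instances = []
    shapes: dict[tuple, list[str]] = {}
    for i, row in df.iterrows():
        path = root / str(row["filename"])
        if not path.exists():
            raise FileNotFoundError(
                f"row {i} of {table}: file {path} does not exist"
            )
        series = load_series(path)
        shapes.setdefault(series.data.shape[1:], []).append(str(row["filename"]))
        instances.append(
            TaskInstance(
                subject_id=str(row["subject_id"]),
                class_label=int(row["class_label"]),
                trait=float(row["trait"]),
                series=series.data,
                tr=series.tr,
            )
        )
    if len(shapes) > 1:
        detail = "; ".join(f"{shp}: {names[:3]}" for shp, names in shapes.items())
        raise ValueError(f"inconsistent spatial shapes across files: {detail}")
    return instances
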