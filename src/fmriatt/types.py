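"""Shared domain containers."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class TaskInstance:
    """One labelled 4D fMRI recording.

    series is ordered (t, x, y, z); trait is a subject-level score shared by
    every instance of the same subject (the regression target in transfer
    workflows, analogous to a fluid-intelligence measure).
    """

    subject_id: str
    class_label: int
    trait: float
    series: np.ndarray
    tr: float = 1.0

    @property
    def n_frames(self) -> int:
        return self.series.shape[0]

    @property
    def grid(self) -> tuple[int, int, int]:
        return self.series.shape[1:4]


@dataclass
class VolumeSeries:
    """A 4D volume series with its voxel-to-world transform."""

    data: np.ndarray  # (t, x, y, z)
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    tr: float = 1.0

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"series must be 4D (t,x,y,z); got {self.data.ndim}D")
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine must be invertible")
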