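"""Data containers for labeled-volume morphometrics."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

CELL_TYPES = ("inflammatory", "fibroblastic", "endocardial", "undefined")

NM3_TO_UM3 = 1e-9
NM2_TO_UM2 = 1e-6


@dataclass
class LabeledVolume:
    """3D integer voxel labels with anisotropic pitch.

    ``labels`` is indexed ``(z, y, x)``; 0 is extracellular matrix /
    background. ``voxel_pitch`` is ``(dz, dy, dx)`` in nm. Every nonzero
    label gets a cell type from ``type_table``; labels missing from the
    table default to ``"undefined"`` with a warning.
    """

    labels: np.ndarray
    voxel_pitch: tuple[float, float, float]
    type_table: dict[int, str] = field(default_factory=dict)
    nucleus_table: dict[int, bool] | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(f"labels must be 3D (z, y, x), got ndim={self.labels.ndim}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError(f"labels must be integer, got dtype={self.labels.dtype}")
        if self.labels.min() < 0:
            raise ValueError("labels must be >= 0")
        if len(self.voxel_pitch) != 3 or any(p <= 0 for p in self.voxel_pitch):
            raise ValueError(f"voxel_pitch must be 3 positive values, got {self.voxel_pitch}")
        for lab, t in self.type_table.items():
            if t not in CELL_TYPES:
                raise ValueError(f"unknown cell type {t!r} for label {lab}")
        present = set(int(v) for v in np.unique(self.labels)) - {0}
        missing = present - set(self.type_table)
        if missing:
            warnings.warn(
                f"labels {sorted(missing)} absent from type_table; defaulting to 'undefined'",
                stacklevel=2,
            )
            for lab in missing:
                self.type_table[lab] = "undefined"

    @property
    def voxel_volume_nm3(self) -> float:
        dz, dy, dx = self.voxel_pitch
        return dz * dy * dx

    def cell_type(self, label: int) -> str:
        return self.type_table.get(int(label), "undefined")

    def present_labels(self) -> list[int]:
        """Sorted nonzero labels present in the volume."""
        return [int(v) for v in np.unique(self.labels) if v != 0]


@dataclass
class CellMorphometry:
    """Per-cell volume and surface area.

    ``volume`` is in μm³ (exact from voxel counts), ``surface_area`` in
    μm² (sum of anisotropic voxel-face areas against any different value,
    stack-boundary faces included). ``touches_boundary`` flags cells cut
    by the stack border; they are kept, not excluded.
    """

    label: int
    cell_type: str
    voxel_count: int
    volume: float
    surface_area: float
    touches_boundary: bool
    has_nucleus: bool | None = None


@dataclass
class ContactInterface:
    """Shared-face interface between two cells (``label_a < label_b``).

    ``area`` is the sum of shared voxel-face areas in μm², each face
    weighted by the anisotropic face area of its orientation.
    ``patch_count`` is the number of connected components of the shared
    face set.
    """

    label_a: int
    label_b: int
    shared_face_count: int
    area: float
    patch_count: int

    def __post_init__(self) -> None:
        if self.label_a >= self.label_b:
            raise ValueError("require label_a < label_b")
        if (self.area > 0) != (self.shared_face_count > 0):
            raise ValueError("area > 0 iff shared_face_count > 0")


@dataclass
class TypeSummary:
    """Per-cell-type aggregate statistics of a contact graph."""

    cell_type: str
    cell_count: int
    total_volume: float
    mean_volume: float
    volume_fraction: float
    mean_interfacing_cells: float
    mean_contact_area_per_interface: float
    mean_relative_contact_area: float
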