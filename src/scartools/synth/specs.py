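"""Validated specifications and ground-truth records for synthetic data."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, field_validator, model_validator


class SheetSpec(BaseModel):
    """Specification of a synthetic 2D voltage-amplitude sheet.

    ``electrode_center`` is a continuous ``(row, col)`` pixel coordinate.
    ``lambda_scar`` / ``lambda_uninjured`` are the region space constants
    in mm; ``v_edge`` the amplitude (a.u.) at the region edge closest to
    the electrode. ``mode`` selects the observation model: a pure
    exponential radial decay law, or the steady state of the passive
    cable equation on the sheet.
    """

    model_config = ConfigDict(arbitrary_types_allowed=True)

    grid_shape: tuple[int, int]
    pixel_pitch: float  # mm / pixel
    electrode_center: tuple[float, float]  # (row, col), continuous
    scar_mask: np.ndarray
    lambda_scar: float  # mm
    lambda_uninjured: float  # mm
    v_edge: float  # a.u.
    noise_sd: float = 0.0  # a.u.
    mode: Literal["pure_exponential", "cable_steady_state"] = "pure_exponential"
    seed: int = 0

    @field_validator("pixel_pitch", "lambda_scar", "lambda_uninjured", "v_edge")
    @classmethod
    def _positive(cls, v, info):
        if v <= 0:
            raise ValueError(f"{info.field_name} must be > 0, got {v}")
        return v

    @field_validator("noise_sd")
    @classmethod
    def _nonneg(cls, v):
        if v < 0:
            raise ValueError(f"noise_sd must be >= 0, got {v}")
        return v

    @model_validator(mode="after")
    def _check_mask(self):
        mask = np.asarray(self.scar_mask, dtype=bool)
        if mask.shape != tuple(self.grid_shape):
            raise ValueError(
                f"scar_mask shape {mask.shape} does not match grid_shape {self.grid_shape}"
            )
        object.__setattr__(self, "scar_mask", mask)
        er, ec = self.electrode_center
        rr, cc = int(round(er)), int(round(ec))
        if 0 <= rr < mask.shape[0] and 0 <= cc < mask.shape[1] and mask[rr, cc]:
            raise ValueError("scar_mask contains electrode_center")
        return self


class CellSpec(BaseModel):
    """One prescribed synthetic cell.

    ``center`` is a continuous ``(z, y, x)`` voxel coordinate (voxel i
    spans [i, i+1), centers at i+0.5). ``size`` is in nm: a single radius
    for spheres, three semi-axes for ellipsoids, three full edge lengths
    for boxes and sheets (a sheet is a slab — a box thin along one axis).
    A voxel belongs to the cell when its center lies inside the physical
    shape.
    """

    cell_type: Literal["inflammatory", "fibroblastic", "endocardial", "undefined"]
    shape: Literal["sphere", "ellipsoid", "sheet", "box"]
    size: tuple[float, ...]  # nm
    center: tuple[float, float, float]  # voxel coordinates (z, y, x)
    label: Optional[int] = None

    @model_validator(mode="after")
    def _check_size(self):
        expected = 1 if self.shape == "sphere" else 3
        if len(self.size) != expected:
            raise ValueError(
                f"shape {self.shape!r} takes {expected} size parameter(s), got {len(self.size)}"
            )
        if any(s <= 0 for s in self.size):
            raise ValueError(f"size parameters must be > 0, got {self.size}")
        return self


class ContactPlanEntry(BaseModel):
    """A pair of prescribed cells required to share a face patch.

    ``area_nm2``, when given, is the required shared-face area; the
    realized area must match it within ``rel_tol``.
    """

    label_a: int
    label_b: int
    area_nm2: Optional[float] = None
    rel_tol: float = 0.05

    @model_validator(mode="after")
    def _ordered(self):
        if self.label_a >= self.label_b:
            raise ValueError("require label_a < label_b")
        return self


class VolumeSpec(BaseModel):
    """Specification of a synthetic labeled voxel volume."""

    grid_shape: tuple[int, int, int]  # (z, y, x) voxels
    voxel_pitch: tuple[float, float, float]  # (dz, dy, dx) nm
    cells: list[CellSpec] = []
    target_cell_fraction: Optional[float] = None
    contact_plan: list[ContactPlanEntry] = []
    seed: int = 0

    @field_validator("voxel_pitch")
    @classmethod
    def _positive_pitch(cls, v):
        if any(p <= 0 for p in v):
            raise ValueError(f"voxel_pitch must be positive, got {v}")
        return v

    @field_validator("grid_shape")
    @classmethod
    def _positive_shape(cls, v):
        if any(n <= 0 for n in v):
            raise ValueError(f"grid_shape must be positive, got {v}")
        return v

    @field_validator("target_cell_fraction")
    @classmethod
    def _fraction(cls, v):
        if v is not None and not (0.0 <= v <= 1.0):
            raise ValueError(f"target_cell_fraction must be in [0, 1], got {v}")
        return v


@dataclass
class MapGroundTruth:
    """Ground truth emitted with every synthetic map or movie."""

    lambda_scar: float
    lambda_uninjured: float
    v_edge: float
    noise_sd: float
    seed: int
    mode: str
    r_edge_scar_mm: float
    r_edge_uninjured_mm: float
    warnings: list[str] = field(default_factory=list)
    pulse_window: tuple[int, int] | None = None
    n_frames: int | None = None

    def to_dict(self) -> dict:
        d = {
            "lambda_scar": self.lambda_scar,
            "lambda_uninjured": self.lambda_uninjured,
            "v_edge": self.v_edge,
            "noise_sd": self.noise_sd,
            "seed": self.seed,
            "mode": self.mode,
            "r_edge_scar_mm": self.r_edge_scar_mm,
            "r_edge_uninjured_mm": self.r_edge_uninjured_mm,
            "warnings": list(self.warnings),
        }
        if self.pulse_window is not None:
            d["pulse_window"] = list(self.pulse_window)
        if self.n_frames is not None:
            d["n_frames"] = self.n_frames
        return d


@dataclass
class VolumeGroundTruth:
    """Ground truth emitted with every synthetic labeled volume."""

    voxel_counts: dict[int, int]
    volumes_nm3: dict[int, float]
    contact_areas_nm2: dict[tuple[int, int], float]
    cell_fraction: float
    cell_types: dict[int, str]
    seed: int
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "voxel_counts": {str(k): v for k, v in self.voxel_counts.items()},
            "volumes_nm3": {str(k): v for k, v in self.volumes_nm3.items()},
            "contact_areas_nm2": {f"{a}-{b}": v for (a, b), v in self.contact_areas_nm2.items()},
            "cell_fraction": self.cell_fraction,
            "cell_types": {str(k): v for k, v in self.cell_types.items()},
            "seed": self.seed,
            "warnings": list(self.warnings),
        }
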