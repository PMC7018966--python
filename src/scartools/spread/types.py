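"""Data containers for the passive-spread (decay-constant) pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class VoltageMovie:
    """Fluorescence movie: ``frames[t, row, col]`` in arbitrary units.

    Parameters
    ----------
    frames
        3D float array, shape ``(t, rows, cols)``.
    frame_rate
        Acquisition rate in frames per second.
    pixel_pitch
        Physical pixel size in mm/pixel.
    """

    frames: np.ndarray
    frame_rate: float
    pixel_pitch: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError(f"frames must be 3D (t, row, col), got ndim={self.frames.ndim}")
        if self.frame_rate <= 0:
            raise ValueError(f"frame_rate must be > 0, got {self.frame_rate}")
        if self.pixel_pitch <= 0:
            raise ValueError(f"pixel_pitch must be > 0, got {self.pixel_pitch}")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


@dataclass
class AmplitudeMap:
    """2D map of maximal voltage amplitude (a.u.), with pixel pitch in mm."""

    values: np.ndarray
    pixel_pitch: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError(f"values must be 2D, got ndim={self.values.ndim}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("amplitude map contains non-finite values")
        if np.any(self.values < 0):
            raise ValueError("amplitude map contains negative values")
        if self.pixel_pitch <= 0:
            raise ValueError(f"pixel_pitch must be > 0, got {self.pixel_pitch}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class RegionAnnotation:
    """Analysis regions on an amplitude map.

    ``electrode_center`` is a continuous ``(row, col)`` pixel coordinate;
    it must lie outside the scar. ``uninjured_mask`` is optional — when
    absent a matched region can be constructed by rotation
    (:func:`scartools.spread.select_matched_uninjured_region`).
    """

    scar_mask: np.ndarray
    electrode_center: tuple[float, float]
    uninjured_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.scar_mask = np.asarray(self.scar_mask, dtype=bool)
        if self.scar_mask.ndim != 2:
            raise ValueError("scar_mask must be 2D")
        r, c = self.electrode_center
        rr, cc = int(round(r)), int(round(c))
        if (
            0 <= rr < self.scar_mask.shape[0]
            and 0 <= cc < self.scar_mask.shape[1]
            and self.scar_mask[rr, cc]
        ):
            raise ValueError("electrode_center lies inside scar_mask")
        if self.uninjured_mask is not None:
            self.uninjured_mask = np.asarray(self.uninjured_mask, dtype=bool)
            if self.uninjured_mask.shape != self.scar_mask.shape:
                raise ValueError("uninjured_mask shape differs from scar_mask")
            if np.any(self.uninjured_mask & self.scar_mask):
                raise ValueError("uninjured_mask overlaps scar_mask")

    def validate_shape(self, shape: tuple[int, int]) -> None:
        if self.scar_mask.shape != tuple(shape):
            raise ValueError(
                f"annotation shape {self.scar_mask.shape} does not match map shape {tuple(shape)}"
            )


@dataclass
class AmplitudeBin:
    """One isopotential bin: an equal-width amplitude interval of a map region.

    ``index`` 1 is the highest-amplitude bin (closest to the electrode).
    ``mean_distance`` is edge-referenced: 0 mm at the region edge closest
    to the electrode.
    """

    index: int
    amplitude_range: tuple[float, float]
    mean_amplitude: float
    mean_distance: float
    pixel_count: int
    merged: bool = False


@dataclass
class DecayFit:
    """Single-exponential fit V(d) = v_edge * exp(-d / decay_constant).

    ``decay_constant`` is in mm: the distance at which the fitted amplitude
    falls to 1/e (~37%) of the fitted amplitude at distance 0.
    """

    v_edge: float
    decay_constant: float
    bins: list[AmplitudeBin]
    rss: float
    r_squared: float
    converged: bool
    message: str = ""

    def predict(self, distance) -> np.ndarray:
        """Evaluate the fitted curve at ``distance`` (mm)."""
        d = np.asarray(distance, dtype=float)
        return self.v_edge * np.exp(-d / self.decay_constant)

    def to_dict(self) -> dict:
        return {
            "v_edge": self.v_edge,
            "decay_constant": self.decay_constant,
            "rss": self.rss,
            "r_squared": self.r_squared,
            "converged": self.converged,
            "message": self.message,
            "bins": [
                {
                    "index": b.index,
                    "amplitude_range": list(b.amplitude_range),
                    "mean_amplitude": b.mean_amplitude,
                    "mean_distance": b.mean_distance,
                    "pixel_count": b.pixel_count,
                    "merged": b.merged,
                }
                for b in self.bins
            ],
        }


@dataclass
class GroupSummary:
    """Per-group decay constants with mean, SEM, and control-normalized mean."""

    label: str
    decay_constants: list[float]
    mean: float = field(init=False)
    sem: float = field(init=False)
    normalized_mean: float | None = None
    percent_change_vs_control: float | None = None

    def __post_init__(self) -> None:
        if len(self.decay_constants) == 0:
            raise ValueError(f"group {self.label!r} has no decay constants")
        arr = np.asarray(self.decay_constants, dtype=float)
        self.mean = float(arr.mean())
        # SEM uses the sample standard deviation (ddof=1); 0 for n=1.
        self.sem = float(arr.std(ddof=1) / np.sqrt(arr.size)) if arr.size > 1 else 0.0

    @property
    def n(self) -> int:
        return len(self.decay_constants)
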