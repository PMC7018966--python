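"""Readers and writers: multi-page TIFF stacks with JSON sidecars.

Physical metadata (pixel pitch, frame rate, voxel pitch, masks, ground
truth) always travels in a JSON sidecar named ``<file>.json`` next to the
TIFF — TIFF tags are not trusted for it. Masks are run-length encoded
over the row-major flattened array.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Any

import numpy as np
import tifffile
import yaml

from .morpho.types import CELL_TYPES, LabeledVolume
from .spread.types import AmplitudeMap, RegionAnnotation, VoltageMovie
from .synth.specs import CellSpec, ContactPlanEntry, SheetSpec, VolumeSpec

__all__ = [
    "rle_encode",
    "rle_decode",
    "read_movie_tiff",
    "write_movie_tiff",
    "read_map_tiff",
    "write_map_tiff",
    "read_label_tiff",
    "write_label_tiff",
    "read_annotation_json",
    "write_annotation_json",
    "load_config",
    "sheet_spec_from_config",
    "volume_spec_from_config",
]


# ---------------------------------------------------------------------------
# mask run-length encoding

def rle_encode(mask: np.ndarray) -> dict:
    """Run-length encode a boolean mask (row-major runs of True)."""
    mask = np.asarray(mask, dtype=bool)
    flat = mask.ravel()
    padded = np.r_[False, flat, False]
    changes = np.nonzero(np.diff(padded.astype(np.int8)))[0]
    starts = changes[0::2]
    ends = changes[1::2]
    return {
        "shape": list(mask.shape),
        "starts": starts.tolist(),
        "lengths": (ends - starts).tolist(),
    }


def rle_decode(d: dict) -> np.ndarray:
    """Inverse of :func:`rle_encode`."""
    shape = tuple(d["shape"])
    flat = np.zeros(int(np.prod(shape)), dtype=bool)
    for s, n in zip(d["starts"], d["lengths"]):
        flat[s : s + n] = True
    return flat.reshape(shape)


# ---------------------------------------------------------------------------
# sidecar helpers

def _sidecar_path(path: Path) -> Path:
    return Path(str(path) + ".json")


def _read_sidecar(path: Path) -> dict:
    sc = _sidecar_path(path)
    if not sc.exists():
        raise FileNotFoundError(f"sidecar {sc} not found next to {path}")
    with open(sc) as fh:
        return json.load(fh)


def _require(sidecar: dict, field: str, path: Path) -> Any:
    if field not in sidecar:
        raise ValueError(f"sidecar of {path} is missing required field {field!r}")
    return sidecar[field]


def _write_sidecar(path: Path, payload: dict) -> None:
    with open(_sidecar_path(path), "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# movies and maps

def write_movie_tiff(path, movie: VoltageMovie, extra: dict | None = None) -> None:
    """Multi-page TIFF (page order = frame order) plus JSON sidecar."""
    path = Path(path)
    tifffile.imwrite(path, movie.frames.astype(np.float32))
    payload = {"kind": "movie", "frame_rate": movie.frame_rate, "pixel_pitch_mm": movie.pixel_pitch}
    payload.update(extra or {})
    _write_sidecar(path, payload)


def read_movie_tiff(path) -> VoltageMovie:
    path = Path(path)
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    sc = _read_sidecar(path)
    return VoltageMovie(
        frames=np.asarray(frames, dtype=float),
        frame_rate=float(_require(sc, "frame_rate", path)),
        pixel_pitch=float(_require(sc, "pixel_pitch_mm", path)),
    )


def write_map_tiff(path, amap: AmplitudeMap, extra: dict | None = None) -> None:
    path = Path(path)
    tifffile.imwrite(path, amap.values.astype(np.float32))
    payload = {"kind": "amplitude_map", "pixel_pitch_mm": amap.pixel_pitch}
    payload.update(extra or {})
    _write_sidecar(path, payload)


def read_map_tiff(path) -> AmplitudeMap:
    path = Path(path)
    values = tifffile.imread(path)
    sc = _read_sidecar(path)
    return AmplitudeMap(
        values=np.asarray(values, dtype=float),
        pixel_pitch=float(_require(sc, "pixel_pitch_mm", path)),
    )


# ---------------------------------------------------------------------------
# label volumes

def write_label_tiff(path, vol: LabeledVolume, extra: dict | None = None) -> None:
    """Multi-page TIFF (page order = z) plus JSON sidecar with pitch and tables."""
    path = Path(path)
    tifffile.imwrite(path, vol.labels.astype(np.int32))
    payload = {
        "kind": "label_volume",
        "voxel_pitch_nm": list(vol.voxel_pitch),
        "type_table": {str(k): v for k, v in vol.type_table.items()},
    }
    if vol.nucleus_table is not None:
        payload["nucleus_table"] = {str(k): bool(v) for k, v in vol.nucleus_table.items()}
    payload.update(extra or {})
    _write_sidecar(path, payload)


def read_label_tiff(path) -> LabeledVolume:
    path = Path(path)
    labels = tifffile.imread(path)
    if labels.ndim == 2:
        labels = labels[None]
    sc = _read_sidecar(path)
    pitch = _require(sc, "voxel_pitch_nm", path)
    raw_table = sc.get("type_table", {})
    type_table = {}
    for k, v in raw_table.items():
        if v not in CELL_TYPES:
            warnings.warn(f"unknown cell type {v!r} for label {k}; using 'undefined'", stacklevel=2)
            v = "undefined"
        type_table[int(k)] = v
    nucleus_table = None
    if "nucleus_table" in sc:
        nucleus_table = {int(k): bool(v) for k, v in sc["nucleus_table"].items()}
    return LabeledVolume(
        labels=np.asarray(labels).astype(np.int32),
        voxel_pitch=tuple(float(p) for p in pitch),
        type_table=type_table,
        nucleus_table=nucleus_table,
    )


# ---------------------------------------------------------------------------
# annotations

def write_annotation_json(path, annotation: RegionAnnotation) -> None:
    payload = {
        "electrode_center": list(annotation.electrode_center),
        "scar_mask_rle": rle_encode(annotation.scar_mask),
    }
    if annotation.uninjured_mask is not None:
        payload["uninjured_mask_rle"] = rle_encode(annotation.uninjured_mask)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


def read_annotation_json(path) -> RegionAnnotation:
    path = Path(path)
    with open(path) as fh:
        d = json.load(fh)
    if "electrode_center" not in d:
        raise ValueError(f"annotation {path} is missing required field 'electrode_center'")
    if "scar_mask_rle" not in d:
        raise ValueError(f"annotation {path} is missing required field 'scar_mask_rle'")
    unj = rle_decode(d["uninjured_mask_rle"]) if "uninjured_mask_rle" in d else None
    return RegionAnnotation(
        scar_mask=rle_decode(d["scar_mask_rle"]),
        electrode_center=tuple(d["electrode_center"]),
        uninjured_mask=unj,
    )


def annotation_from_sidecar(d: dict) -> RegionAnnotation | None:
    """Build a RegionAnnotation from sidecar fields, if present."""
    if "electrode_center" not in d or "scar_mask_rle" not in d:
        return None
    unj = rle_decode(d["uninjured_mask_rle"]) if "uninjured_mask_rle" in d else None
    return RegionAnnotation(
        scar_mask=rle_decode(d["scar_mask_rle"]),
        electrode_center=tuple(d["electrode_center"]),
        uninjured_mask=unj,
    )


# ---------------------------------------------------------------------------
# configs

def load_config(path) -> dict:
    """Load a JSON or YAML config file into a dict."""
    path = Path(path)
    with open(path) as fh:
        if path.suffix in (".yaml", ".yml"):
            return yaml.safe_load(fh)
        return json.load(fh)


def _mask_from_config(entry: dict, shape: tuple[int, int], center) -> np.ndarray:
    from .synth.maps import sector_mask

    if "rle" in entry:
        mask = rle_decode(entry["rle"])
        if mask.shape != tuple(shape):
            raise ValueError(f"RLE mask shape {mask.shape} does not match grid {shape}")
        return mask
    if "sector" in entry:
        s = entry["sector"]
        return sector_mask(
            tuple(shape),
            tuple(s.get("center", center)),
            float(s["r_inner_px"]),
            float(s["r_outer_px"]),
            float(s["angle_start_deg"]),
            float(s["angle_end_deg"]),
        )
    raise ValueError("scar_mask config must contain either 'rle' or 'sector'")


def sheet_spec_from_config(cfg: dict) -> SheetSpec:
    """Build a SheetSpec from a config dict (mask as RLE or sector params)."""
    shape = tuple(cfg["grid_shape"])
    center = tuple(cfg["electrode_center"])
    return SheetSpec(
        grid_shape=shape,
        pixel_pitch=float(cfg["pixel_pitch"]),
        electrode_center=center,
        scar_mask=_mask_from_config(cfg["scar_mask"], shape, center),
        lambda_scar=float(cfg["lambda_scar"]),
        lambda_uninjured=float(cfg["lambda_uninjured"]),
        v_edge=float(cfg["v_edge"]),
        noise_sd=float(cfg.get("noise_sd", 0.0)),
        mode=cfg.get("mode", "pure_exponential"),
        seed=int(cfg.get("seed", 0)),
    )


def volume_spec_from_config(cfg: dict) -> VolumeSpec:
    return VolumeSpec(
        grid_shape=tuple(cfg["grid_shape"]),
        voxel_pitch=tuple(cfg["voxel_pitch"]),
        cells=[CellSpec(**c) for c in cfg.get("cells", [])],
        target_cell_fraction=cfg.get("target_cell_fraction"),
        contact_plan=[ContactPlanEntry(**e) for e in cfg.get("contact_plan", [])],
        seed=int(cfg.get("seed", 0)),
    )
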