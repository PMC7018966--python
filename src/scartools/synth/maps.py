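"""Synthetic amplitude maps and voltage movies with known ground truth."""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from ..spread.types import AmplitudeMap, VoltageMovie
from .specs import MapGroundTruth, SheetSpec

__all__ = ["generate_amplitude_map", "generate_voltage_movie", "sector_mask"]


def sector_mask(
    shape: tuple[int, int],
    center: tuple[float, float],
    r_inner_px: float,
    r_outer_px: float,
    angle_start_deg: float,
    angle_end_deg: float,
) -> np.ndarray:
    """Annulus-sector mask around ``center``; angles in degrees, 0 = +col axis.

    Convenience for building scar/uninjured region fixtures. Angles wrap
    modulo 360.
    """
    rows, cols = np.indices(shape)
    dr = rows - center[0]
    dc = cols - center[1]
    r = np.hypot(dr, dc)
    theta = np.rad2deg(np.arctan2(dr, dc)) % 360.0
    a0 = angle_start_deg % 360.0
    a1 = angle_end_deg % 360.0
    if a0 <= a1:
        ang_ok = (theta >= a0) & (theta <= a1)
    else:
        ang_ok = (theta >= a0) | (theta <= a1)
    return (r >= r_inner_px) & (r <= r_outer_px) & ang_ok


def _radius_mm(spec: SheetSpec) -> np.ndarray:
    rows, cols = np.indices(spec.grid_shape)
    er, ec = spec.electrode_center
    return np.hypot(rows - er, cols - ec) * spec.pixel_pitch


def generate_amplitude_map(spec: SheetSpec) -> tuple[AmplitudeMap, MapGroundTruth]:
    """Generate a synthetic maximal-amplitude map.

    ``pure_exponential``: each pixel gets
    ``v_edge * exp(-(r - r_edge) / lambda_region)`` where r is the
    continuous Euclidean distance (mm) from the electrode center to the
    pixel center and r_edge is the minimum r over the region's mask
    (scar pixels use the scar law; all other pixels the uninjured law).

    ``cable_steady_state``: the steady-state solution of
    ``lambda^2 * laplacian(V) - V = 0`` with a unit current source at the
    electrode pixel (5-point finite differences, Dirichlet V=0 border,
    per-pixel region-dependent lambda), scaled so its maximum equals
    ``v_edge``.

    Additive i.i.d. Gaussian noise with ``noise_sd`` is applied last and
    the result clipped at 0 (amplitude maps are nonnegative). Identical
    spec + seed gives bit-identical output.
    """
    scar = spec.scar_mask
    if not scar.any():
        raise ValueError("scar_mask is empty")
    warnings_list: list[str] = []
    for name, lam in (("lambda_scar", spec.lambda_scar), ("lambda_uninjured", spec.lambda_uninjured)):
        if lam < spec.pixel_pitch:
            warnings_list.append(
                f"{name}={lam} mm is smaller than one pixel pitch ({spec.pixel_pitch} mm); "
                "decay is unresolvable at this sampling"
            )

    r = _radius_mm(spec)
    r_edge_scar = float(r[scar].min())
    uninjured = ~scar
    r_edge_unj = float(r[uninjured].min()) if uninjured.any() else 0.0

    if spec.mode == "pure_exponential":
        values = np.where(
            scar,
            spec.v_edge * np.exp(-(r - r_edge_scar) / spec.lambda_scar),
            spec.v_edge * np.exp(-(r - r_edge_unj) / spec.lambda_uninjured),
        )
    else:
        values = _cable_steady_state(spec)
        values *= spec.v_edge / values.max()

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        values = values + rng.normal(0.0, spec.noise_sd, size=values.shape)
    values = np.clip(values, 0.0, None)

    gt = MapGroundTruth(
        lambda_scar=spec.lambda_scar,
        lambda_uninjured=spec.lambda_uninjured,
        v_edge=spec.v_edge,
        noise_sd=spec.noise_sd,
        seed=spec.seed,
        mode=spec.mode,
        r_edge_scar_mm=r_edge_scar,
        r_edge_uninjured_mm=r_edge_unj,
        warnings=warnings_list,
    )
    return AmplitudeMap(values=values, pixel_pitch=spec.pixel_pitch), gt


def _cable_steady_state(spec: SheetSpec) -> np.ndarray:
    """Sparse 5-point solve of lambda^2 ∇²V - V = -delta_source, V=0 on border."""
    nrow, ncol = spec.grid_shape
    h = spec.pixel_pitch
    lam2 = np.where(spec.scar_mask, spec.lambda_scar**2, spec.lambda_uninjured**2)

    idx = np.arange(nrow * ncol).reshape(nrow, ncol)
    interior = np.zeros((nrow, ncol), dtype=bool)
    interior[1:-1, 1:-1] = True

    rows_i, cols_i = np.nonzero(interior)
    n_int = rows_i.size
    eq = -np.ones((nrow, ncol), dtype=int)
    eq[interior] = np.arange(n_int)

    coef = lam2[rows_i, cols_i] / h**2
    diag = -4.0 * coef - 1.0
    data = [diag]
    ii = [np.arange(n_int)]
    jj = [np.arange(n_int)]
    for drow, dcol in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        nr, nc = rows_i + drow, cols_i + dcol
        neigh = eq[nr, nc]
        sel = neigh >= 0  # Dirichlet V=0 outside interior: dropped terms
        ii.append(np.arange(n_int)[sel])
        jj.append(neigh[sel])
        data.append(coef[sel])
    mat = sp.csr_matrix(
        (np.concatenate(data), (np.concatenate(ii), np.concatenate(jj))), shape=(n_int, n_int)
    )

    rhs = np.zeros(n_int)
    er, ec = spec.electrode_center
    src_r = int(np.clip(round(er), 1, nrow - 2))
    src_c = int(np.clip(round(ec), 1, ncol - 2))
    rhs[eq[src_r, src_c]] = -1.0

    v_int = spla.spsolve(mat, rhs)
    v = np.zeros((nrow, ncol))
    v[interior] = v_int
    return v


def generate_voltage_movie(
    spec: SheetSpec,
    frames: int,
    pulse_window: tuple[int, int],
    frame_rate: float = 1000.0,
) -> tuple[VoltageMovie, MapGroundTruth]:
    """Generate a synthetic movie: baseline noise plus a pulsed amplitude image.

    Frames in ``pulse_window`` (half-open ``[start, end)``) carry the
    noise-free amplitude image of :func:`generate_amplitude_map`; all
    frames get i.i.d. Gaussian noise of ``spec.noise_sd``. Applying
    :func:`scartools.spread.compute_amplitude_map` with the same window
    recovers the map within noise (exactly when ``noise_sd=0``).
    """
    start, end = pulse_window
    if not (0 <= start < end <= frames):
        raise ValueError(f"pulse_window {pulse_window} invalid for {frames} frames")

    base_spec = spec.model_copy(update={"noise_sd": 0.0})
    amap, gt = generate_amplitude_map(base_spec)

    movie = np.zeros((frames,) + tuple(spec.grid_shape))
    movie[start:end] = amap.values
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        movie += rng.normal(0.0, spec.noise_sd, size=movie.shape)

    gt.noise_sd = spec.noise_sd
    gt.pulse_window = (start, end)
    gt.n_frames = frames
    return (
        VoltageMovie(frames=movie, frame_rate=frame_rate, pixel_pitch=spec.pixel_pitch),
        gt,
    )
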