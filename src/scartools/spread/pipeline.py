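"""Operations of the decay-constant pipeline.

Movie -> maximal amplitude map -> region masking -> equal-width amplitude
bins -> edge-referenced radial distances -> single-exponential fit ->
group summaries.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import curve_fit

from .types import (
    AmplitudeBin,
    AmplitudeMap,
    DecayFit,
    GroupSummary,
    RegionAnnotation,
    VoltageMovie,
)

DEFAULT_N_BINS = 5
MIN_BIN_PIXELS = 5


def compute_amplitude_map(
    movie: VoltageMovie,
    pulse_window: tuple[int, int],
    baseline_window: tuple[int, int] | None = None,
) -> AmplitudeMap:
    """Per-pixel max over the pulse window minus mean over the baseline window.

    ``baseline_window`` defaults to all frames preceding pulse onset.
    Windows are half-open frame ranges ``[start, end)`` and must be
    disjoint and non-empty. Negative results are clipped to 0.
    """
    p0, p1 = pulse_window
    if baseline_window is None:
        baseline_window = (0, p0)
    b0, b1 = baseline_window
    n = movie.n_frames
    for name, (s, e) in (("pulse_window", (p0, p1)), ("baseline_window", (b0, b1))):
        if not (0 <= s < e <= n):
            raise ValueError(f"{name} ({s}, {e}) invalid for movie with {n} frames")
    if max(p0, b0) < min(p1, b1):
        raise ValueError("pulse_window and baseline_window overlap")
    baseline = movie.frames[b0:b1].mean(axis=0)
    peak = movie.frames[p0:p1].max(axis=0)
    values = np.clip(peak - baseline, 0.0, None)
    return AmplitudeMap(values=values, pixel_pitch=movie.pixel_pitch)


def radial_distances(
    mask: np.ndarray,
    electrode_center: tuple[float, float],
    pixel_pitch: float,
) -> np.ndarray:
    """Edge-referenced radial distance image (mm) over ``mask``.

    For each pixel p in the mask, ``d(p) = ||p - electrode_center|| *
    pixel_pitch - r_edge``, with ``r_edge`` the minimum of the first term
    over the mask: 0 mm at the mask edge closest to the electrode.
    Pixels outside the mask are NaN.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    rows, cols = np.indices(mask.shape)
    er, ec = electrode_center
    r = np.hypot(rows - er, cols - ec) * pixel_pitch
    r_edge = r[mask].min()
    out = np.full(mask.shape, np.nan)
    out[mask] = r[mask] - r_edge
    return out


def bin_amplitudes(
    amap: AmplitudeMap,
    mask: np.ndarray,
    electrode_center: tuple[float, float],
    n_bins: int = DEFAULT_N_BINS,
    min_pixels: int = MIN_BIN_PIXELS,
) -> list[AmplitudeBin]:
    """Partition in-mask amplitudes into ``n_bins`` equal-width intervals.

    The [min, max] amplitude range of the masked pixels is split into
    equal-width intervals; the highest interval is closed at the maximum.
    Bin index 1 is the highest-amplitude bin. Each bin carries its mean
    amplitude and mean edge-referenced distance. Bins with fewer than
    ``min_pixels`` pixels are merged into their lower-amplitude neighbor
    and flagged ``merged=True``.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != amap.shape:
        raise ValueError("mask shape does not match amplitude map")
    if not mask.any():
        raise ValueError("mask is empty")
    if n_bins < 2:
        raise ValueError(f"n_bins must be >= 2, got {n_bins}")
    vals = amap.values[mask]
    lo, hi = float(vals.min()), float(vals.max())
    if hi == lo:
        raise ValueError("amplitude map is constant over mask; cannot bin")

    edges = np.linspace(lo, hi, n_bins + 1)
    # np.digitize with right-open intervals; clamp the max into the top bin.
    idx = np.digitize(vals, edges[1:-1], right=False)  # 0 = lowest interval
    dist = radial_distances(mask, electrode_center, amap.pixel_pitch)[mask]

    # Collect per-interval members, highest amplitude first (bin index 1).
    groups: list[dict] = []
    for k in range(n_bins - 1, -1, -1):
        sel = idx == k
        groups.append(
            {
                "range": (float(edges[k]), float(edges[k + 1])),
                "amps": vals[sel],
                "dists": dist[sel],
                "merged": False,
            }
        )

    # Merge under-filled bins downward (into the next lower-amplitude bin,
    # i.e. the following entry in highest-first order).
    merged_groups: list[dict] = []
    i = 0
    while i < len(groups):
        g = groups[i]
        while g["amps"].size < min_pixels and i + 1 < len(groups):
            nxt = groups[i + 1]
            g = {
                "range": (nxt["range"][0], g["range"][1]),
                "amps": np.concatenate([g["amps"], nxt["amps"]]),
                "dists": np.concatenate([g["dists"], nxt["dists"]]),
                "merged": True,
            }
            i += 1
        merged_groups.append(g)
        i += 1
    # A trailing under-filled lowest bin merges upward into the last kept bin.
    if merged_groups and merged_groups[-1]["amps"].size < min_pixels and len(merged_groups) > 1:
        last = merged_groups.pop()
        prev = merged_groups[-1]
        merged_groups[-1] = {
            "range": (last["range"][0], prev["range"][1]),
            "amps": np.concatenate([prev["amps"], last["amps"]]),
            "dists": np.concatenate([prev["dists"], last["dists"]]),
            "merged": True,
        }

    bins = []
    for j, g in enumerate(merged_groups, start=1):
        if g["amps"].size == 0:
            continue
        bins.append(
            AmplitudeBin(
                index=j,
                amplitude_range=g["range"],
                mean_amplitude=float(g["amps"].mean()),
                mean_distance=float(g["dists"].mean()),
                pixel_count=int(g["amps"].size),
                merged=g["merged"],
            )
        )
    return bins


def fit_exponential(bins: list[AmplitudeBin]) -> DecayFit:
    """Nonlinear least squares of mean_amplitude = v_edge * exp(-d / DC).

    Initialized from the log-linear fit. Requires >= 3 usable bins with
    distinct mean distances and positive mean amplitudes. Non-convergence
    or a non-physical decay constant yields ``converged=False`` with
    diagnostics, never a silent failure.
    """
    usable = [b for b in bins if b.mean_amplitude > 0]
    d = np.array([b.mean_distance for b in usable])
    v = np.array([b.mean_amplitude for b in usable])
    if len(usable) < 3 or np.unique(d).size < 3:
        raise ValueError(
            f"need >=3 usable bins with distinct mean distances, got {np.unique(d).size}"
        )

    # Log-linear initialization: log v = log v_edge - d/DC.
    slope, intercept = np.polyfit(d, np.log(v), 1)
    v0_init = float(np.exp(intercept))
    dc_init = float(-1.0 / slope) if slope < 0 else float(d.max() - d.min() or 1.0)

    def model(x, v0, dc):
        return v0 * np.exp(-x / dc)

    converged = True
    message = "ok"
    try:
        popt, _ = curve_fit(
            model, d, v, p0=(v0_init, dc_init), bounds=([0, 1e-12], [np.inf, np.inf]), maxfev=10000
        )
        v0, dc = float(popt[0]), float(popt[1])
    except RuntimeError as exc:  # pragma: no cover - scipy rarely fails here
        v0, dc = v0_init, dc_init
        converged = False
        message = f"curve_fit did not converge: {exc}"

    field_width = float(d.max() - d.min())
    if converged and field_width > 0 and dc > 10 * field_width:
        converged = False
        message = f"decay constant {dc:.3g} mm exceeds 10x the fitted distance span {field_width:.3g} mm"

    resid = v - model(d, v0, dc)
    rss = float(np.sum(resid**2))
    tss = float(np.sum((v - v.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else np.nan
    return DecayFit(
        v_edge=v0,
        decay_constant=dc,
        bins=list(bins),
        rss=rss,
        r_squared=r2,
        converged=converged,
        message=message,
    )


def select_matched_uninjured_region(
    amap: AmplitudeMap,
    annotation: RegionAnnotation,
    margin_px: int = 2,
    angle_step_deg: float = 1.0,
) -> np.ndarray:
    """Construct (or validate) a matched uninjured region mask.

    The matched region has the same pixel count (within 2%) and the same
    minimum electrode distance (within half a pixel) as the scar. It is
    built by rotating the scar mask about the electrode center until the
    rotated copy clears the scar plus a ``margin_px`` dilation. When
    ``annotation.uninjured_mask`` is already present it is validated
    against the same criteria and returned unchanged.
    """
    from scipy.ndimage import binary_dilation

    annotation.validate_shape(amap.shape)
    scar = annotation.scar_mask
    er, ec = annotation.electrode_center
    n_scar = int(scar.sum())
    if n_scar == 0:
        raise ValueError("scar_mask is empty")

    rows, cols = np.nonzero(scar)
    r_scar_min = np.hypot(rows - er, cols - ec).min()

    if annotation.uninjured_mask is not None:
        cand = annotation.uninjured_mask
        _validate_matched(cand, scar, (er, ec), n_scar, r_scar_min)
        return cand

    forbidden = binary_dilation(scar, iterations=margin_px) if margin_px > 0 else scar
    dr = rows - er
    dc = cols - ec
    h, w = scar.shape
    for angle in np.arange(angle_step_deg, 360.0, angle_step_deg):
        t = np.deg2rad(angle)
        cr = dr * np.cos(t) - dc * np.sin(t)
        cc = dr * np.sin(t) + dc * np.cos(t)
        rr = np.round(cr + er).astype(int)
        rcol = np.round(cc + ec).astype(int)
        if rr.min() < 0 or rcol.min() < 0 or rr.max() >= h or rcol.max() >= w:
            continue
        cand = np.zeros_like(scar)
        cand[rr, rcol] = True
        if np.any(cand & forbidden):
            continue
        n_cand = int(cand.sum())
        if abs(n_cand - n_scar) > 0.02 * n_scar:
            continue
        r_cand_min = np.hypot(np.nonzero(cand)[0] - er, np.nonzero(cand)[1] - ec).min()
        if abs(r_cand_min - r_scar_min) > 0.5:
            continue
        return cand
    raise ValueError(
        "no rotation of the scar mask yields a valid matched uninjured region; "
        "annotate the uninjured region manually"
    )


def _validate_matched(cand, scar, center, n_scar, r_scar_min):
    cand = np.asarray(cand, dtype=bool)
    n_cand = int(cand.sum())
    if n_cand == 0:
        raise ValueError("uninjured_mask is empty")
    if np.any(cand & scar):
        raise ValueError("uninjured_mask overlaps scar_mask")
    if abs(n_cand - n_scar) > 0.02 * n_scar:
        raise ValueError(
            f"uninjured_mask pixel count {n_cand} differs from scar's {n_scar} by more than 2%"
        )
    er, ec = center
    r_cand_min = np.hypot(np.nonzero(cand)[0] - er, np.nonzero(cand)[1] - ec).min()
    if abs(r_cand_min - r_scar_min) > 0.5:
        raise ValueError(
            f"uninjured_mask minimum electrode distance {r_cand_min:.2f} px differs from "
            f"scar's {r_scar_min:.2f} px by more than half a pixel"
        )


def pipeline_decay_constant(
    source: VoltageMovie | AmplitudeMap,
    annotation: RegionAnnotation,
    region: str = "scar",
    n_bins: int = DEFAULT_N_BINS,
    pulse_window: tuple[int, int] | None = None,
    baseline_window: tuple[int, int] | None = None,
    min_pixels: int = MIN_BIN_PIXELS,
) -> DecayFit:
    """End-to-end decay-constant computation for one region of one heart.

    ``source`` may be a movie (then ``pulse_window`` is required) or a
    precomputed amplitude map. ``region`` selects ``"scar"`` or
    ``"uninjured"``; a missing uninjured mask is constructed by rotation
    matching. Deterministic for fixed input.
    """
    if isinstance(source, VoltageMovie):
        if pulse_window is None:
            raise ValueError("pulse_window is required when source is a movie")
        amap = compute_amplitude_map(source, pulse_window, baseline_window)
    else:
        amap = source
    annotation.validate_shape(amap.shape)
    if region == "scar":
        mask = annotation.scar_mask
    elif region == "uninjured":
        mask = (
            annotation.uninjured_mask
            if annotation.uninjured_mask is not None
            else select_matched_uninjured_region(amap, annotation)
        )
    else:
        raise ValueError(f"region must be 'scar' or 'uninjured', got {region!r}")
    bins = bin_amplitudes(amap, mask, annotation.electrode_center, n_bins, min_pixels)
    return fit_exponential(bins)


def percent_decrease(group_mean: float, control_mean: float) -> float:
    """Percent decrease of ``group_mean`` relative to ``control_mean``."""
    if control_mean <= 0:
        raise ValueError(f"control_mean must be > 0, got {control_mean}")
    return 100.0 * (control_mean - group_mean) / control_mean


def normalize_to_control(
    groups: list[GroupSummary], control_label: str
) -> list[GroupSummary]:
    """Set each group's normalized mean to group mean / control mean.

    The control group normalizes to exactly 1. Also fills in the percent
    change of each group versus control. Returns the same objects,
    mutated in place, for chaining.
    """
    by_label = {g.label: g for g in groups}
    if control_label not in by_label:
        raise ValueError(f"control group {control_label!r} not found")
    control_mean = by_label[control_label].mean
    if control_mean == 0:
        raise ValueError("control group mean is zero; cannot normalize")
    for g in groups:
        g.normalized_mean = g.mean / control_mean
        g.percent_change_vs_control = percent_decrease(g.mean, control_mean)
    return groups
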