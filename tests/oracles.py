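"""Independent brute-force oracles used by the test suite.

Deliberately slow, loop-based, and written against the definitions only —
they share no code with the package paths they check.
"""

from __future__ import annotations

import numpy as np

NEIGHBOR_OFFSETS = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]


def brute_surface_areas(labels: np.ndarray, pitch: tuple[float, float, float]) -> dict[int, float]:
    """Per-label surface area in nm² by scanning all 6 faces of every voxel.

    Faces against a different value (background, another label, or the
    outside of the stack) count, weighted by orientation.
    """
    dz, dy, dx = pitch
    face = {0: dy * dx, 1: dz * dx, 2: dz * dy}  # axis of the face normal
    nz, ny, nx = labels.shape
    areas: dict[int, float] = {}
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                lab = int(labels[z, y, x])
                if lab == 0:
                    continue
                for oz, oy, ox in NEIGHBOR_OFFSETS:
                    z2, y2, x2 = z + oz, y + oy, x + ox
                    if 0 <= z2 < nz and 0 <= y2 < ny and 0 <= x2 < nx:
                        other = int(labels[z2, y2, x2])
                    else:
                        other = -1  # outside the stack
                    if other != lab:
                        axis = 0 if oz else (1 if oy else 2)
                        areas[lab] = areas.get(lab, 0.0) + face[axis]
    return areas


def brute_contact_areas(
    labels: np.ndarray, pitch: tuple[float, float, float]
) -> dict[tuple[int, int], float]:
    """All-pairs shared-face areas in nm² by scanning every voxel pair."""
    dz, dy, dx = pitch
    face = {0: dy * dx, 1: dz * dx, 2: dz * dy}
    nz, ny, nx = labels.shape
    out: dict[tuple[int, int], float] = {}
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                a = int(labels[z, y, x])
                if a == 0:
                    continue
                # forward neighbors only, to count each face once
                for axis, (oz, oy, ox) in enumerate([(1, 0, 0), (0, 1, 0), (0, 0, 1)]):
                    z2, y2, x2 = z + oz, y + oy, x + ox
                    if not (z2 < nz and y2 < ny and x2 < nx):
                        continue
                    b = int(labels[z2, y2, x2])
                    if b == 0 or b == a:
                        continue
                    pair = (min(a, b), max(a, b))
                    out[pair] = out.get(pair, 0.0) + face[axis]
    return out


def brute_voxel_counts(labels: np.ndarray) -> dict[int, int]:
    counts: dict[int, int] = {}
    for v in labels.ravel():
        v = int(v)
        if v:
            counts[v] = counts.get(v, 0) + 1
    return counts


def sphere_voxel_count(radius_vox: float, center: tuple[float, float, float], shape) -> int:
    """Voxel-center-in-sphere count (isotropic, voxel coordinates)."""
    n = 0
    for z in range(shape[0]):
        for y in range(shape[1]):
            for x in range(shape[2]):
                d2 = (
                    (z + 0.5 - center[0]) ** 2
                    + (y + 0.5 - center[1]) ** 2
                    + (x + 0.5 - center[2]) ** 2
                )
                if d2 <= radius_vox**2:
                    n += 1
    return n


def brute_bin_members(values: np.ndarray, mask: np.ndarray, n_bins: int) -> list[set]:
    """Per-pixel equal-width bin assignment; returns pixel-index sets.

    Bin 0 is the highest-amplitude bin, matching the package's index-1
    convention. The top interval is closed at the max.
    """
    vals = values[mask]
    lo, hi = vals.min(), vals.max()
    width = (hi - lo) / n_bins
    members = [set() for _ in range(n_bins)]
    for idx in np.argwhere(mask):
        v = values[tuple(idx)]
        k = int((v - lo) / width)
        if k >= n_bins:
            k = n_bins - 1
        members[n_bins - 1 - k].add(tuple(idx))
    return members


def radial_cable_oracle(lam: float, r0: float = 0.01, r_max: float = 20.0, n: int = 8000):
    """Dense 1D FD solve of lam^2 (V'' + V'/r) - V = 0, V(r0)=1, V(r_max)=0."""
    import scipy.sparse as sp
    import scipy.sparse.linalg as spla

    r = np.linspace(r0, r_max, n)
    h = r[1] - r[0]
    ri = r[1:-1]
    main = np.full(n - 2, -2 * lam**2 / h**2 - 1.0)
    up = lam**2 / h**2 + lam**2 / (2 * ri * h)
    dn = lam**2 / h**2 - lam**2 / (2 * ri * h)
    mat = sp.diags([dn[1:], main, up[:-1]], [-1, 0, 1], format="csr")
    rhs = np.zeros(n - 2)
    rhs[0] = -dn[0] * 1.0  # V(r0) = 1
    v = spla.spsolve(mat, rhs)
    return r, np.r_[1.0, v, 0.0]


def exponential_fit_lambda(r: np.ndarray, v: np.ndarray) -> float:
    """Log-linear single-exponential fit; returns the decay constant."""
    slope, _ = np.polyfit(r, np.log(v), 1)
    return -1.0 / slope
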