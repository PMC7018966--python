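"""Shared fixtures: small synthetic fixtures with analytically known truth."""

from __future__ import annotations

import numpy as np
import pytest

from scartools.morpho import LabeledVolume
from scartools.spread import RegionAnnotation
from scartools.synth import SheetSpec, sector_mask

PITCH_MM = 0.0928  # camera pixel pitch used throughout the map fixtures
EM_PITCH = (80.0, 6.3, 6.3)  # (dz, dy, dx) nm


def make_sector_spec(
    lambda_scar: float = 0.48,
    lambda_uninjured: float = 0.57,
    noise_sd: float = 0.0,
    seed: int = 0,
    shape: tuple[int, int] = (220, 220),
    pixel_pitch: float = PITCH_MM,
    mode: str = "pure_exponential",
    depth_lambdas: float = 3.0,
    r_inner_mm: float = 2.0,
) -> SheetSpec:
    """Sector-shaped scar starting ``r_inner_mm`` from a central electrode."""
    center = ((shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0)
    r0 = r_inner_mm / pixel_pitch
    r1 = r0 + depth_lambdas * lambda_scar / pixel_pitch
    mask = sector_mask(shape, center, r0, r1, 30.0, 70.0)
    return SheetSpec(
        grid_shape=shape,
        pixel_pitch=pixel_pitch,
        electrode_center=center,
        scar_mask=mask,
        lambda_scar=lambda_scar,
        lambda_uninjured=lambda_uninjured,
        v_edge=10.0,
        noise_sd=noise_sd,
        mode=mode,
        seed=seed,
    )


@pytest.fixture
def sector_spec() -> SheetSpec:
    return make_sector_spec()


@pytest.fixture
def sector_annotation(sector_spec) -> RegionAnnotation:
    return RegionAnnotation(
        scar_mask=sector_spec.scar_mask, electrode_center=sector_spec.electrode_center
    )


def two_box_labels(axis: int = 0, n: int = 10) -> np.ndarray:
    """Two n³ boxes sharing one full n×n face, stacked along ``axis``."""
    shape = [n, n, n]
    shape[axis] = 2 * n
    labels = np.zeros(shape, dtype=np.int32)
    lead = [slice(None)] * 3
    trail = [slice(None)] * 3
    lead[axis] = slice(0, n)
    trail[axis] = slice(n, 2 * n)
    labels[tuple(lead)] = 1
    labels[tuple(trail)] = 2
    return labels


@pytest.fixture
def two_box_volume() -> LabeledVolume:
    return LabeledVolume(
        labels=two_box_labels(axis=0),
        voxel_pitch=(1000.0, 1000.0, 1000.0),
        type_table={1: "inflammatory", 2: "fibroblastic"},
    )


def random_label_volume(rng: np.random.Generator, shape=(16, 16, 16), n_labels: int = 4):
    """Random blobby label volume for oracle-equivalence tests."""
    labels = rng.integers(0, n_labels + 1, size=shape).astype(np.int32)
    return LabeledVolume(labels=labels, voxel_pitch=EM_PITCH, type_table={})
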