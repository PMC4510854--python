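"""Shared fixtures: session-scoped synthetic volumes with planted truth."""

import numpy as np
import pytest

from cytoarch3d.synthetic_data import (
    CellGenParams,
    TomoGenParams,
    generate_cell_volume,
    generate_tomogram_volume,
)


@pytest.fixture(scope="session")
def small_cell():
    """One small (~4×8×4 µm) cell with planted fractions 0.23/0.16."""
    return generate_cell_volume(CellGenParams.small(seed=1))


@pytest.fixture(scope="session")
def tiny_cell_params():
    """A minimal full-featured cell for fast contract tests (~2 s)."""
    return CellGenParams.small(
        seed=5,
        cell_width_um=3.2,
        cell_height_um=6.5,
        cell_depth_um=3.2,
        n_ribbons=3,
        n_terminals=10,
        terminal_radius_nm=300.0,
    )


@pytest.fixture(scope="session")
def tiny_cell(tiny_cell_params):
    return generate_cell_volume(tiny_cell_params)


@pytest.fixture(scope="session")
def tomo_volume():
    """Default-scale tomogram phantom (reference per-context link counts)."""
    return generate_tomogram_volume(TomoGenParams(seed=3))


@pytest.fixture(scope="session")
def small_tomo():
    """Scaled-down tomogram for fast contract tests."""
    return generate_tomogram_volume(TomoGenParams.scaled(0.15, seed=9))


def brute_force_min_distance_nm(coords_a, coords_b, voxel_size):
    """All-pairs minimal voxel-centre distance between two index sets (nm)."""
    sx, sy, sz = voxel_size
    scale = np.array([sz, sy, sx], dtype=float)
    a = np.asarray(coords_a, dtype=float) * scale
    b = np.asarray(coords_b, dtype=float) * scale
    best = np.inf
    for chunk in np.array_split(a, max(1, len(a) // 512)):
        d2 = ((chunk[:, None, :] - b[None, :, :]) ** 2).sum(axis=2)
        best = min(best, float(d2.min()))
    return float(np.sqrt(best))
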