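"""Point-grid construction, classification, and volume-fraction estimation."""

import numpy as np
import pytest

from cytoarch3d.cell_geometry import build_cell_frame
from cytoarch3d.io_formats import LabelVolume
from cytoarch3d.stereology import classify_points, make_point_grid, volume_fraction

VS = (19.0, 19.0, 50.0)


def test_cube_grid_point_count():
    """A 2×2×2 µm cube sampled at 200 nm holds a 10×10×10 interior lattice."""
    vs = (100.0, 100.0, 100.0)
    mask = np.zeros((24, 24, 24), dtype=bool)
    mask[2:22, 2:22, 2:22] = True  # 2 µm cube
    grid = make_point_grid(mask, vs, spacing_nm=(200.0,) * 3, offset=(100.0, 100.0, 100.0))
    labels = np.zeros(mask.shape, dtype=np.uint8)
    labels[mask] = 1
    vol = LabelVolume(labels, vs, {1: "cell"})
    grid = classify_points(grid, vol)
    inside = int(np.sum(grid.classes != "not_in_cell"))
    assert inside == 1000


def test_spacing_below_voxel_size_is_refused():
    mask = np.ones((4, 4, 4), dtype=bool)
    with pytest.raises(ValueError, match="sub-voxel"):
        make_point_grid(mask, VS, spacing_nm=(5.0, 5.0, 100.0), offset=(0, 0, 0))


def test_classification_equals_brute_force_lookup(tiny_cell):
    vol, _ = tiny_cell
    frame = build_cell_frame(vol)
    grid = make_point_grid(frame.infranuclear, vol.voxel_size, rng=7)
    grid = classify_points(grid, vol, frame)
    from cytoarch3d.stereology import _CLASS_OF_SEMANTIC

    sx, sy, sz = vol.voxel_size
    for i in range(0, grid.n_points, 17):  # independent per-point lookup
        x, y, z = grid.points_nm[i]
        lab = int(vol.voxels[int(round(z / sz)), int(round(y / sy)), int(round(x / sx))])
        expected = "not_in_cell" if lab == 0 else _CLASS_OF_SEMANTIC[vol.label_table[lab]]
        assert grid.classes[i] == expected


def test_point_in_mitochondrion_is_classified_as_such():
    vs = (10.0, 10.0, 10.0)
    labels = np.zeros((9, 9, 9), dtype=np.uint8)
    labels[:, :, :] = 1
    labels[4, 4, 4] = 2
    vol = LabelVolume(labels, vs, {1: "cell", 2: "mitochondrion"})
    mask = labels > 0
    grid = make_point_grid(mask, vs, spacing_nm=(40.0, 40.0, 40.0), offset=(0, 0, 0))
    grid = classify_points(grid, vol)
    # the lattice point at (40, 40, 40) nm sits in the centre voxel
    hit = np.all(np.isclose(grid.points_nm, [40.0, 40.0, 40.0]), axis=1)
    assert grid.classes[hit][0] == "mitochondrion"


def test_sphere_fraction_converges_to_analytic():
    """Unbiasedness on an analytic solid: sphere of radius r in a cube of
    side 4r; point fraction → (4/3)πr³/(4r)³."""
    vs = (25.0, 25.0, 25.0)
    n = 80  # 2 µm cube at 25 nm voxels
    r_nm = 500.0
    zz, yy, xx = np.mgrid[0:n, 0:n, 0:n]
    c = (n - 1) / 2
    sphere = ((xx - c) ** 2 + (yy - c) ** 2 + (zz - c) ** 2) * vs[0] ** 2 <= r_nm**2
    labels = np.ones((n, n, n), dtype=np.uint8)
    labels[sphere] = 2
    vol = LabelVolume(labels, vs, {1: "cell", 2: "mitochondrion"})
    grid = make_point_grid(labels > 0, vs, spacing_nm=(100.0,) * 3, rng=3)
    grid = classify_points(grid, vol)
    est = volume_fraction(grid, class_set=("mitochondrion",))
    expected = (4 / 3) * np.pi * r_nm**3 / 2000.0**3
    assert est.fraction == pytest.approx(expected, abs=2 * max(est.se, 0.002))


def test_offset_shift_changes_estimates_by_less_than_2se(small_cell):
    vol, _ = small_cell
    frame = build_cell_frame(vol)
    ests = []
    for off in ((0.0, 0.0, 0.0), (100.0, 100.0, 100.0)):
        grid = make_point_grid(frame.infranuclear, vol.voxel_size, offset=off)
        grid = classify_points(grid, vol, frame)
        idx = vol.nm_to_index(grid.points_nm)
        in_region = frame.infranuclear[idx[:, 0], idx[:, 1], idx[:, 2]]
        sel = in_region & (grid.hemisphere_tags["flat_round"] == "flat")
        ests.append(volume_fraction(grid, region=sel, region_name="flat"))
    assert abs(ests[0].fraction - ests[1].fraction) < 2 * max(e.se for e in ests)


def test_whole_cell_grid_exceeds_5000_points(small_cell):
    vol, _ = small_cell
    frame = build_cell_frame(vol)
    grid = make_point_grid(frame.infranuclear, vol.voxel_size, rng=0)
    grid = classify_points(grid, vol, frame)
    assert int(np.sum(grid.classes != "not_in_cell")) > 5000


def test_fractions_invariant_under_label_renumbering():
    vs = (10.0, 10.0, 10.0)
    labels = np.ones((8, 8, 8), dtype=np.uint16)
    labels[2:4] = 7
    vol1 = LabelVolume(labels, vs, {1: "cell", 7: "membrane"})
    relab = np.where(labels == 7, 900, 30).astype(np.uint16)
    vol2 = LabelVolume(relab, vs, {30: "cell", 900: "membrane"})
    grid = make_point_grid(labels > 0, vs, spacing_nm=(20.0, 20.0, 20.0), offset=(0, 0, 0))
    e1 = volume_fraction(classify_points(grid, vol1), class_set=("membrane",))
    e2 = volume_fraction(classify_points(grid, vol2), class_set=("membrane",))
    assert e1.fraction == e2.fraction
    assert e1.n_points == e2.n_points


def test_empty_region_is_an_error(tiny_cell):
    vol, _ = tiny_cell
    frame = build_cell_frame(vol)
    grid = classify_points(
        make_point_grid(frame.infranuclear, vol.voxel_size, rng=1), vol, frame
    )
    with pytest.raises(ValueError, match="no in-cell points"):
        volume_fraction(grid, region=np.zeros(grid.n_points, dtype=bool))
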