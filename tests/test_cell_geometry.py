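"""Centre line, hemisphere partitions, flatness and infranuclear extent."""

import numpy as np
import pytest

from cytoarch3d.cell_geometry import (
    build_cell_frame,
    cell_mask_from_volume,
    dynamic_centre_line,
    flatness_profile,
    infranuclear_mask,
    partition_hemispheres,
)
from cytoarch3d.synthetic_data import CellGenParams, generate_cell_volume

VS = (19.0, 19.0, 50.0)


def cylinder_mask(nz=20, ny=40, nx=30, r=10, cx=15, cy=20):
    zz, yy, xx = np.mgrid[0:nz, 0:ny, 0:nx]
    return (xx - cx) ** 2 + (yy - cy) ** 2 <= r**2


def test_centre_line_of_cylinder_is_its_axis():
    mask = cylinder_mask()
    line = dynamic_centre_line(mask, VS)
    assert np.allclose(line[:, 0], 15 * VS[0], atol=VS[0] / 2)
    assert np.allclose(line[:, 1], 20 * VS[1], atol=VS[1] / 2)


def test_centre_line_translation_equivariance():
    mask = cylinder_mask(cx=12, cy=18, r=8)
    shifted = np.roll(mask, (3, 5), axis=(1, 2))
    l0 = dynamic_centre_line(mask, VS)
    l1 = dynamic_centre_line(shifted, VS)
    assert np.allclose(l1[:, 0] - l0[:, 0], 5 * VS[0])
    assert np.allclose(l1[:, 1] - l0[:, 1], 3 * VS[1])


def test_centre_line_rejects_interior_gap():
    mask = cylinder_mask()
    mask[7] = False
    with pytest.raises(ValueError, match="section"):
        dynamic_centre_line(mask, VS)


def test_partition_is_exact_and_balanced_on_cylinder():
    mask = cylinder_mask()
    line = dynamic_centre_line(mask, VS)
    parts = partition_hemispheres(mask, line, "flat_round", VS)
    union = parts["flat"] | parts["round"]
    assert np.array_equal(union, mask)
    assert not (parts["flat"] & parts["round"]).any()
    n_flat, n_round = parts["flat"].sum(), parts["round"].sum()
    # symmetric cylinder: halves equal up to one section row of voxels
    assert abs(int(n_flat) - int(n_round)) <= mask.shape[0] * (2 * 10 + 1)


def test_partition_axis_validation():
    mask = cylinder_mask()
    line = dynamic_centre_line(mask, VS)
    with pytest.raises(ValueError, match="axis_choice"):
        partition_hemispheres(mask, line, "up_down", VS)


def test_generated_cell_centre_line_and_hemispheres(small_cell):
    vol, truth = small_cell
    cell = cell_mask_from_volume(vol)
    line = dynamic_centre_line(cell, vol.voxel_size)
    sx = vol.voxel_size[0]
    for rec in truth.tables["centre_line"]:
        iz = rec["z_index"]
        assert abs(line[iz, 0] - rec["cx_nm"]) <= sx  # within one in-plane voxel
    parts = partition_hemispheres(cell, line, "flat_round", vol.voxel_size, flat_sign=-1)
    agree = tot = 0
    for rec in truth.tables["centre_line"]:
        iz = rec["z_index"]
        ys, xs = np.nonzero(cell[iz])
        truth_flat = (xs * sx - rec["cx_nm"]) * -1 > 0
        agree += int((parts["flat"][iz][ys, xs] == truth_flat).sum())
        tot += len(xs)
    assert agree / tot >= 0.98


def test_flatness_zero_for_rectangular_prism():
    mask = np.zeros((9, 60, 30), dtype=bool)
    mask[:, 5:55, 8:22] = True
    prof = flatness_profile(
        mask, VS, bands_um=((0.1, 0.3), (0.35, 0.5)), neck_y_nm=50 * VS[1]
    )
    assert prof.deviation_nm["neg_x"] == pytest.approx([0.0, 0.0], abs=1e-9)
    assert prof.deviation_nm["pos_x"] == pytest.approx([0.0, 0.0], abs=1e-9)
    assert prof.tied


def test_flatness_hemicylinder_matches_mean_sagitta():
    """One flat face, one circular face: the flat side's deviation is zero and
    the curved side's mean deviation over the full chord is the analytic mean
    sagitta R(1 − π/4) of the arc."""
    ny, nx = 220, 120
    R_nm = 80 * VS[0]
    yy2, xx2 = np.mgrid[0:ny, 0:nx]
    u = (yy2 - 110) / 100.0  # chord coordinate along the long axis
    xmax_nm = 10 * VS[0] + R_nm * np.sqrt(np.clip(1 - u**2, 0, 1))
    sec = (np.abs(u) <= 1.0) & (xx2 >= 10) & (xx2 * VS[0] <= xmax_nm)
    mask = np.repeat(sec[None, :, :], 3, axis=0)
    prof = flatness_profile(
        mask,
        VS,
        bands_um=((0.0, 200 * VS[1] / 1000),),  # the full chord
        neck_y_nm=210 * VS[1],
    )
    expected = R_nm * (1 - np.pi / 4)
    assert prof.deviation_nm["pos_x"][0] == pytest.approx(expected, abs=1.5 * VS[0])
    assert prof.deviation_nm["neg_x"][0] == pytest.approx(0.0, abs=1.0 * VS[0])
    assert prof.flat_sign == -1


@pytest.mark.parametrize("seed", range(12))
def test_flatter_side_identified(seed):
    """With a 3:1 bulge contrast the flattened side is always identified."""
    params = CellGenParams.shape_only(seed=100 + seed, cell_height_um=13.0,
                                      cell_width_um=5.0, cell_depth_um=5.0)
    vol, truth = generate_cell_volume(params)
    frame = build_cell_frame(vol)
    assert frame.flat_sign == truth.summary["flat_side_sign"]


def test_infranuclear_matches_truth_exactly(tiny_cell):
    vol, truth = tiny_cell
    cell = cell_mask_from_volume(vol)
    nucleus = vol.mask("nucleus")
    mask, zwin = infranuclear_mask(cell, nucleus, vol.voxel_size)
    sy = vol.voxel_size[1]
    y_cut = int(np.floor(truth.summary["y_nucleus_basal_nm"] / sy))
    expected = cell.copy()
    expected[:, y_cut:, :] = False
    # same definition: strictly below the nucleus' basal-most voxel
    y_basal_vox = np.nonzero(nucleus.any(axis=(0, 2)))[0].min()
    expected = cell.copy()
    expected[:, y_basal_vox:, :] = False
    assert np.array_equal(mask, expected)
    # the peri-nuclear window is 3 µm thick: 60 sections at 50 nm
    assert zwin[1] - zwin[0] + 1 == pytest.approx(60, abs=1)


def test_infranuclear_requires_nucleus():
    mask = cylinder_mask()
    with pytest.raises(ValueError, match="nucleus"):
        infranuclear_mask(mask, np.zeros_like(mask), VS)


def test_nucleus_at_apex_keeps_whole_cell_below():
    mask = np.zeros((10, 50, 30), dtype=bool)
    mask[:, 2:50, 8:22] = True
    nucleus = np.zeros_like(mask)
    nucleus[3:7, 46:50, 12:18] = True
    infra, _ = infranuclear_mask(mask, nucleus, VS)
    assert np.array_equal(infra[:, :46, :], mask[:, :46, :])
    assert not infra[:, 46:, :].any()
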