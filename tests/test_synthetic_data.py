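"""Generator contracts: determinism, planted-parameter fidelity, invariants."""

import numpy as np
import pytest

from cytoarch3d.synthetic_data import (
    CellGenParams,
    GeometryInfeasibleError,
    SheetAreaMixture,
    TomoGenParams,
    generate_cell_volume,
    generate_tomogram_volume,
    sample_sheet_areas,
)


def test_fixed_seed_cell_is_bit_identical(tiny_cell_params, tiny_cell):
    vol2, truth2 = generate_cell_volume(tiny_cell_params)
    assert np.array_equal(tiny_cell[0].voxels, vol2.voxels)
    assert tiny_cell[1].summary["hemisphere_fractions"] == truth2.summary["hemisphere_fractions"]


def test_planted_hemisphere_fractions_match_targets(small_cell):
    _, truth = small_cell
    fr = truth.summary["hemisphere_fractions"]
    assert fr["flat"] == pytest.approx(0.23, abs=0.01)
    assert fr["round"] == pytest.approx(0.16, abs=0.01)


def test_anterior_posterior_plant():
    p = CellGenParams.small(
        seed=11,
        membrane_fraction_flat=None,
        membrane_fraction_round=None,
        membrane_fraction_anterior=0.21,
        membrane_fraction_posterior=0.19,
    )
    _, truth = generate_cell_volume(p)
    fr = truth.summary["hemisphere_fractions"]
    assert fr["anterior"] == pytest.approx(0.21, abs=0.01)
    assert fr["posterior"] == pytest.approx(0.19, abs=0.01)


def test_both_fraction_axes_rejected():
    with pytest.raises(ValueError, match="one hemisphere axis"):
        CellGenParams.small(seed=0, membrane_fraction_anterior=0.2, membrane_fraction_posterior=0.2)


def test_terminal_placement_is_binomial():
    """Mean flattened-terminal count over many cells matches n·p (binomial oracle)."""
    n_cells, n_t, p_flat = 40, 16, 0.63
    counts = []
    for seed in range(n_cells):
        params = CellGenParams.shape_only(seed=seed, n_terminals=n_t, terminal_radius_nm=250.0)
        _, truth = generate_cell_volume(params)
        counts.append(sum(1 for t in truth.tables["terminals"] if t["hemisphere"] == "flat"))
    se = np.sqrt(n_t * p_flat * (1 - p_flat) / n_cells)
    assert np.mean(counts) == pytest.approx(n_t * p_flat, abs=3 * se)


def test_labels_are_mutually_exclusive_and_traceable(tiny_cell):
    vol, truth = tiny_cell
    present = {int(v) for v in np.unique(vol.voxels)} - {0}
    assert present == set(vol.label_table)  # every labeled voxel traces to the table
    # truth tables are self-consistent with the census
    counts = truth.summary["n_sheets_by_type"]
    assert sum(counts.values()) == len(truth.tables["sheets"])
    sheet_labels = {s["label"] for s in truth.tables["sheets"]}
    assert sheet_labels == {l for l, c in vol.label_table.items() if c == "membrane"}


def test_nucleus_voxel_count_matches_analytic(tiny_cell):
    """Voxel counting of a planted solid agrees with its analytic volume
    within one voxel-shell of the surface."""
    vol, truth = tiny_cell
    p = truth.params
    a = p["cell_width_um"] * 1000 / 2
    c = p["cell_depth_um"] * 1000 / 2
    H = p["cell_height_um"] * 1000
    semi = np.array([0.55 * a, 0.15 * H, 0.55 * c])  # nucleus semi-axes (x, y, z)
    analytic = 4 / 3 * np.pi * semi.prod()
    sx, sy, sz = vol.voxel_size
    vvox = sx * sy * sz
    counted = int(vol.mask("nucleus").sum()) * vvox
    surface = 4 * np.pi * ((semi[0] * semi[1]) ** 1.6 / 3 + (semi[0] * semi[2]) ** 1.6 / 3
                           + (semi[1] * semi[2]) ** 1.6 / 3) ** (1 / 1.6)
    shell = surface * max(vol.voxel_size)
    assert abs(counted - analytic) <= shell


def test_ribbon_distance_plant_and_truth_agree(small_cell):
    _, truth = small_cell
    ribbons = truth.tables["ribbons"]
    planted = np.array([r["planted_t3_distance_nm"] for r in ribbons])
    measured = np.array([r["nearest_sheet_distance_nm"]["type3"] for r in ribbons])
    # the recorded truth is the exact post-hoc distance; it must sit within a
    # couple of voxels of each ribbon's planted stand-off
    assert np.all(np.abs(planted - measured) < 60.0)


def test_infeasible_geometry_raises_named_error():
    with pytest.raises(GeometryInfeasibleError, match="Type 3"):
        generate_cell_volume(
            CellGenParams.small(seed=0, sheet_area_mixture=SheetAreaMixture(counts=(2, 3, 2)))
        )


def test_sheet_area_mixture_sampler_counts():
    areas, labels = sample_sheet_areas(SheetAreaMixture.reference_scale(), rng=0)
    assert len(areas) == 3 + 8 + 2073
    assert np.all(areas > 0)
    assert [int((labels == t).sum()) for t in (1, 2, 3)] == [3, 8, 2073]


# ---------------------------------------------------------------------------
# tomogram generator
# ---------------------------------------------------------------------------


def test_tomo_zero_counts_gives_membranes_only():
    p = TomoGenParams(
        counts={k: 0 for k in TomoGenParams().counts}, n_free_vesicles=0, seed=0
    )
    vol, truth = generate_tomogram_volume(p)
    classes = set(vol.label_table.values())
    assert classes <= {"membrane", "ribbon"}
    assert truth.tables["links"] == []


def test_tomo_fixed_seed_is_bit_identical(small_tomo):
    vol2, _ = generate_tomogram_volume(TomoGenParams.scaled(0.15, seed=9))
    assert np.array_equal(small_tomo[0].voxels, vol2.voxels)


def test_tomo_planted_link_means_near_configured(tomo_volume):
    _, truth = tomo_volume
    params = TomoGenParams()
    for ctx, rec in truth.summary["per_context"].items():
        m = params.link_length_means[ctx]
        sd = params.link_length_sds[ctx]
        se = sd / np.sqrt(rec["n"])
        assert rec["mean_length_nm"] == pytest.approx(m, abs=3 * se + 2.0)


def test_tomo_vesicle_voxelization_within_one_voxel(tomo_volume):
    vol, truth = tomo_volume
    h = vol.voxel_size[0]
    ves = truth.tables["vesicles"]
    # per-vesicle: the rasterized equivalent-sphere diameter is within one
    # voxel of the sampled diameter
    from cytoarch3d.tomo_links import vesicle_diameters

    measured = {v.vesicle_id: v.diameter_nm for v in vesicle_diameters(vol)}
    errs = [abs(measured[v["label"]] - v["diameter_nm"]) for v in ves]
    assert np.quantile(errs, 0.95) <= h
    assert max(errs) <= 2 * h
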