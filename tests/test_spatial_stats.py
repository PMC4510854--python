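"""Association, densities, distances, terminals, region shares, group tests."""

import numpy as np
import pytest

from cytoarch3d.cell_geometry import build_cell_frame
from cytoarch3d.io_formats import LabelVolume
from cytoarch3d.sheet_assembly import Sheet, Strand, assemble_sheets
from cytoarch3d.spatial_stats import (
    AssociationRecord,
    games_howell,
    mito_density_per_type,
    mito_membrane_association,
    region_membrane_share,
    ribbon_to_sheet_distances,
    run_group_tests,
    terminal_distribution,
)
from conftest import brute_force_min_distance_nm

VS = (19.0, 19.0, 50.0)


def _sheet_from_mask(mask3d, class_label, sheet_id=0, area=1.0):
    strands = []
    for z in range(mask3d.shape[0]):
        ys, xs = np.nonzero(mask3d[z])
        if len(ys):
            pix = np.column_stack([ys, xs])
            strands.append(Strand(z=z, pixels=pix, skeleton=pix, length_nm=len(ys) * VS[0]))
    sh = Sheet(id=sheet_id, strands=strands, z_extent=(0, mask3d.shape[0] - 1))
    sh.class_label = class_label
    sh.area_um2 = area
    return sh


def _truth_typed_sheets(vol, truth):
    """Recovered sheets carrying their planted type (via the label volume)."""
    sheets, *_ = assemble_sheets(vol, classify=False)
    type_of_label = {s["label"]: s["type"] for s in truth.tables["sheets"]}
    for sh in sheets:
        zz, yy, xx = sh.voxel_indices()
        sh.class_label = type_of_label[int(vol.voxels[zz[0], yy[0], xx[0]])]
    return sheets


def test_face_contact_is_zero_gap_and_associated():
    labels = np.zeros((5, 9, 9), dtype=np.uint16)
    labels[:, :, :] = 1
    labels[2, 4, 4] = 10  # membrane voxel
    labels[2, 4, 5] = 40  # mitochondrion voxel sharing a face
    vol = LabelVolume(labels, VS, {1: "cell", 10: "membrane", 40: "mitochondrion"})
    mem = np.zeros(labels.shape, dtype=bool)
    mem[2, 4, 4] = True
    sheets = [_sheet_from_mask(mem, class_label=3)]
    recs, summary = mito_membrane_association(vol, sheets)
    assert recs[0].gap_nm == 0.0
    assert recs[0].associated
    assert summary["associated_fraction"] == 1.0


def test_association_recovery_on_generated_cell(small_cell):
    vol, truth = small_cell
    sheets = _truth_typed_sheets(vol, truth)
    recs, summary = mito_membrane_association(vol, sheets)
    p_true = truth.summary["association_fraction"]
    assert summary["associated_fraction"] == pytest.approx(
        p_true, abs=2 * summary["associated_se"] + 1e-9
    )
    # per-mitochondrion agreement with the planted association flags
    flags = {m["label"]: m["associated"] for m in truth.tables["mitochondria"]}
    rec_by = {r.mito_id: r.associated for r in recs}
    agree = sum(1 for lab, f in flags.items() if rec_by[lab] == f)
    assert agree == len(flags)


def test_association_monotone_in_threshold(tiny_cell):
    vol, truth = tiny_cell
    sheets = _truth_typed_sheets(vol, truth)
    fracs = []
    for thr in (0.0, 19.0, 60.0, 200.0):
        _, s = mito_membrane_association(vol, sheets, gap_threshold_nm=thr)
        fracs.append(s["associated_fraction"])
    assert all(a <= b + 1e-12 for a, b in zip(fracs, fracs[1:]))


@pytest.mark.parametrize("trial", range(6))
def test_min_distances_equal_brute_force_small_volumes(trial):
    rng = np.random.default_rng(200 + trial)
    labels = np.zeros((12, 30, 30), dtype=np.uint16)
    labels[:] = 1
    # one membrane blob, one mitochondrion blob, one ribbon
    def blob(label, n=60):
        while True:
            seed = (int(rng.integers(2, 9)), int(rng.integers(4, 25)), int(rng.integers(4, 25)))
            if labels[seed] == 1:
                break
        pts = {seed}
        for _ in range(20 * n):
            if len(pts) >= n:
                break
            pz, py, px = list(pts)[rng.integers(0, len(pts))]
            q = (
                int(np.clip(pz + rng.integers(-1, 2), 0, 11)),
                int(np.clip(py + rng.integers(-1, 2), 0, 29)),
                int(np.clip(px + rng.integers(-1, 2), 0, 29)),
            )
            if labels[q] == 1:
                pts.add(q)
        for p in pts:
            labels[p] = label
    blob(10)
    blob(40)
    blob(60, n=20)
    vol = LabelVolume(labels, VS, {1: "cell", 10: "membrane", 40: "mitochondrion", 60: "ribbon"})
    mem_mask = labels == 10
    sheets = [_sheet_from_mask(mem_mask, class_label=3)]
    recs, _ = mito_membrane_association(vol, sheets)
    expected = brute_force_min_distance_nm(np.argwhere(labels == 40), np.argwhere(mem_mask), VS)
    assert recs[0].distance_nm == pytest.approx(expected, abs=1e-6)
    drecs, _ = ribbon_to_sheet_distances(vol, sheets)
    centre = np.argwhere(labels == 60).astype(float).mean(axis=0)
    sx, sy, sz = VS
    centre_nm = np.array([centre[2] * sx, centre[1] * sy, centre[0] * sz])
    mem_nm = np.column_stack(
        [np.argwhere(mem_mask)[:, 2] * sx, np.argwhere(mem_mask)[:, 1] * sy,
         np.argwhere(mem_mask)[:, 0] * sz]
    )
    expected_r = float(np.sqrt(((mem_nm - centre_nm) ** 2).sum(axis=1)).min())
    assert drecs[0].distance_by_type_nm[3] == pytest.approx(expected_r, abs=1e-6)


def test_ribbon_distance_recovery_on_generated_cell(small_cell):
    vol, truth = small_cell
    sheets = _truth_typed_sheets(vol, truth)
    drecs, table = ribbon_to_sheet_distances(vol, sheets)
    truth_by_label = {r["label"]: r for r in truth.tables["ribbons"]}
    rec3 = []
    tru3 = []
    for r in drecs:
        t = truth_by_label[r.ribbon_id]
        rec3.append(r.distance_by_type_nm[3])
        tru3.append(t["nearest_sheet_distance_nm"]["type3"])
    # the measured distance reproduces the exact planted truth per ribbon
    assert np.allclose(rec3, tru3, atol=1.5 * max(VS))
    se = np.std(tru3, ddof=1) / np.sqrt(len(tru3))
    assert np.mean(rec3) == pytest.approx(np.mean(tru3), abs=2 * se)


def test_ribbon_on_sheet_distance_is_zero():
    labels = np.ones((5, 9, 9), dtype=np.uint16)
    labels[2, 4, 4] = 60
    mem = np.zeros(labels.shape, dtype=bool)
    mem[2, 4, 4] = True  # sheet passes through the ribbon centre voxel
    mem[2, 4, 5] = True
    vol = LabelVolume(labels, VS, {1: "cell", 60: "ribbon"})
    sheets = [_sheet_from_mask(mem, class_label=3)]
    drecs, _ = ribbon_to_sheet_distances(vol, sheets)
    assert drecs[0].distance_by_type_nm[3] == pytest.approx(0.0, abs=1e-9)


def test_missing_type_reported_as_missing(tiny_cell):
    vol, truth = tiny_cell
    sheets = [s for s in _truth_typed_sheets(vol, truth) if s.class_label == 3]
    drecs, table = ribbon_to_sheet_distances(vol, sheets)
    assert set(drecs[0].distance_by_type_nm) == {3}  # absent types absent, not inf
    assert set(table.type) == {3}


def test_mito_density_example_and_zero():
    recs = [
        AssociationRecord(mito_id=i, distance_nm=0, gap_nm=0, associated=True,
                          gap_by_type_nm={2: 0.0}, types_touched=(2,))
        for i in range(10)
    ]
    df = mito_density_per_type(recs, {2: 4000.0})
    assert df.density_per_um2.item() == pytest.approx(2.5e-3)
    df0 = mito_density_per_type([], {2: 4000.0})
    assert df0.density_per_um2.item() == 0.0
    with pytest.raises(ValueError, match="zero area"):
        mito_density_per_type(recs, {2: 0.0})


def test_density_recomposition(small_cell):
    vol, truth = small_cell
    sheets = _truth_typed_sheets(vol, truth)
    recs, _ = mito_membrane_association(vol, sheets)
    areas = {}
    for sh in sheets:
        areas[sh.class_label] = areas.get(sh.class_label, 0.0) + sh.area_um2
    df = mito_density_per_type(recs, areas)
    total_single = sum(1 for r in recs if r.associated and r.n_types_touched == 1)
    recomposed = float((df.density_per_um2 * df.area_um2).sum())
    assert recomposed == pytest.approx(total_single, rel=1e-9)


def test_terminal_distribution_matches_truth(small_cell):
    vol, truth = small_cell
    frame = build_cell_frame(vol, flat_faces=truth.summary["flat_faces"])
    recs, summary = terminal_distribution(vol, frame)
    tt = truth.tables["terminals"]
    assert summary["counts"]["flat"] == sum(1 for t in tt if t["hemisphere"] == "flat")
    assert summary["counts"]["flat"] + summary["counts"]["round"] == len(tt)
    # the apical-most terminal is the one with the greatest planted height
    apex = max(tt, key=lambda t: t["y_from_base_nm"])
    assert summary["extremum_terminal_id"] == apex["label"]
    # exhaustive per-terminal hemisphere lookup agrees
    truth_sides = {t["label"]: t["hemisphere"] for t in tt}
    for r in recs:
        assert r.hemisphere_flat_round == truth_sides[r.terminal_id]


def test_region_share_identity_and_contract():
    cyto = np.zeros((6, 10, 10), dtype=bool)
    cyto[1:5, 1:9, 1:9] = True
    mem = np.zeros_like(cyto)
    mem[2, 3, 3:7] = True
    sheets = [_sheet_from_mask(mem, class_label=3, area=2.0)]
    vol_share, area_share = region_membrane_share(cyto, sheets, cyto)
    assert (vol_share, area_share) == (1.0, 1.0)
    with pytest.raises(ValueError, match="empty"):
        region_membrane_share(np.zeros_like(cyto), sheets, cyto)


def test_region_share_recovers_planted_box_shares():
    """Box phantom with planted volume/area shares (0.369, 0.688)."""
    from cytoarch3d.synthetic_data import generate_region_share_phantom

    region, cyto, sheet_masks, areas = generate_region_share_phantom(0.369, 0.688)
    sheets = [
        _sheet_from_mask(m, class_label=3, sheet_id=i, area=a)
        for i, (m, a) in enumerate(zip(sheet_masks, areas))
    ]
    vol_share, area_share = region_membrane_share(region, sheets, cyto)
    assert vol_share == pytest.approx(0.369, abs=0.01)
    assert area_share == pytest.approx(0.688, abs=0.01)


# ---------------------------------------------------------------------------
# group tests
# ---------------------------------------------------------------------------


def test_identical_groups_give_null_result():
    x = np.arange(10.0)
    rep = run_group_tests({"a": x, "b": x.copy()}, design="paired")
    assert rep["t_tests"][0]["p"] == pytest.approx(1.0)
    assert rep["t_tests"][0]["t"] == pytest.approx(0.0)


def test_two_separated_groups_detected():
    """Group means 4 standard errors (of the difference) apart at n=20 are
    declared significant in ≥95 % of seeds (power simulation)."""
    hits = 0
    n, trials = 20, 200
    for seed in range(trials):
        rng = np.random.default_rng(seed)
        se_diff = np.sqrt(2.0 / n)
        a = rng.normal(0.0, 1.0, n)
        b = rng.normal(4 * se_diff, 1.0, n)
        rep = run_group_tests({"a": a, "b": b})
        hits += rep["t_tests"][0]["p"] < 0.05
    assert hits / trials >= 0.95


def test_games_howell_matches_reference_implementation():
    """Cross-check the Games–Howell table against pingouin on 3-group data."""
    pingouin = pytest.importorskip("pingouin")
    import pandas as pd

    rng = np.random.default_rng(12)
    data = {
        "g1": rng.normal(10, 2, 12),
        "g2": rng.normal(12, 4, 9),
        "g3": rng.normal(9, 1, 15),
    }
    ours = games_howell(data).set_index(["group_a", "group_b"])
    df = pd.DataFrame(
        [{"group": g, "value": v} for g, vals in data.items() for v in vals]
    )
    ref = pingouin.pairwise_gameshowell(data=df, dv="value", between="group")
    for _, row in ref.iterrows():
        mine = ours.loc[(row.A, row.B)] if (row.A, row.B) in ours.index else ours.loc[(row.B, row.A)]
        assert abs(mine.t) == pytest.approx(abs(row["T"]), rel=1e-6)
        assert mine.df == pytest.approx(row.df, rel=1e-6)
        assert mine.p == pytest.approx(row.pval, abs=1e-6)


def test_group_size_validation():
    with pytest.raises(ValueError, match="fewer than 2"):
        run_group_tests({"a": [1.0], "b": [1.0, 2.0]})
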