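"""Tether morphometry: lengths, contexts, vesicle diameters, comparisons."""

import numpy as np
import pytest

from cytoarch3d.io_formats import LabelVolume
from cytoarch3d.tomo_links import (
    LinkMeasurement,
    compare_contexts,
    measure_link,
    measure_links,
    vesicle_diameters,
)

H = 2.0  # nm, isotropic tomo voxels
VS = (H, H, H)


def _box(shape=(40, 40, 60)):
    return np.zeros(shape, dtype=np.uint16)


def test_straight_tether_length_between_plates():
    """A 30 nm gap bridged by a straight tether measures 30 nm ± one voxel."""
    labels = _box()
    labels[:, :, :5] = 3  # RER slab
    labels[10:30, 10:30, 20:40] = 100  # mitochondrion block
    gap0, gap1 = 5, 20  # voxels 5..19 are the 30 nm gap
    labels[20, 20, gap0:gap1] = 10000
    vol = LabelVolume(labels, VS, {3: "membrane", 100: "mitochondrion", 10000: "tether"})
    m = measure_link(vol, np.argwhere(labels == 10000))
    assert m.context == "mito-RER"
    assert m.attached_both_ends
    assert m.length_nm == pytest.approx(30.0, abs=1.5 * H)


def test_one_ended_tether_contract():
    labels = _box()
    labels[:, :, :5] = 3
    labels[20, 20, 5:15] = 10000  # dangles into empty space
    vol = LabelVolume(labels, VS, {3: "membrane", 10000: "tether"})
    m = measure_link(vol, np.argwhere(labels == 10000))
    assert not m.attached_both_ends
    assert m.length_nm > 0
    assert m.context is None


def test_tether_touching_nothing_is_an_error():
    labels = _box()
    labels[20, 20, 10:20] = 10000
    vol = LabelVolume(labels, VS, {10000: "tether"})
    with pytest.raises(ValueError, match="touches no structure"):
        measure_link(vol, np.argwhere(labels == 10000))


def test_skeleton_length_at_least_chord():
    """Path inequality: skeleton arc length ≥ straight end-to-end length."""
    labels = _box((30, 60, 60))
    labels[:, :5, :] = 3
    labels[10:20, 40:55, 10:25] = 1000
    # an L-shaped tether
    labels[15, 5:40, 12] = 10000
    labels[15, 39, 13:14] = 10000
    vol = LabelVolume(labels, VS, {3: "membrane", 1000: "vesicle", 10000: "tether"})
    m = measure_link(vol, np.argwhere(labels == 10000))
    assert m.length_nm >= m.straight_length_nm - 1e-9


def test_link_rotation_invariance():
    """Rotating the volume 90° in-plane leaves the measured length within a voxel."""
    labels = _box()
    labels[:, :, :5] = 3
    labels[12:28, 12:28, 24:40] = 1000
    labels[20, 20, 5:24] = 10000
    vol = LabelVolume(labels, VS, {3: "membrane", 1000: "vesicle", 10000: "tether"})
    m0 = measure_link(vol, np.argwhere(labels == 10000))
    rot = np.rot90(labels, axes=(1, 2)).copy()
    vol_r = LabelVolume(rot, VS, {3: "membrane", 1000: "vesicle", 10000: "tether"})
    m1 = measure_link(vol_r, np.argwhere(rot == 10000))
    assert m1.length_nm == pytest.approx(m0.length_nm, abs=H)


def test_recovery_of_planted_context_means(tomo_volume):
    vol, truth = tomo_volume
    links = measure_links(vol)
    rec = {l.link_id: l for l in links}
    by_ctx: dict = {}
    for r in truth.tables["links"]:
        by_ctx.setdefault(r["context"], []).append(
            (r["length_nm"], rec[r["label"]].length_nm, rec[r["label"]].context)
        )
    for ctx, rows in by_ctx.items():
        planted = np.array([a for a, _, _ in rows])
        measured = np.array([b for _, b, _ in rows])
        assert all(c == ctx for _, _, c in rows)  # context recovery
        se = planted.std(ddof=1) / np.sqrt(len(planted))
        assert measured.mean() == pytest.approx(planted.mean(), abs=2 * se)


def test_vesicle_diameter_of_rasterized_sphere():
    labels = _box()
    zz, yy, xx = np.mgrid[0:40, 0:40, 0:60]
    r = 37.3 / 2 / H
    sphere = (zz - 20) ** 2 + (yy - 20) ** 2 + (xx - 30) ** 2 <= r**2
    labels[sphere] = 1000
    vol = LabelVolume(labels, VS, {1000: "vesicle"})
    (v,) = vesicle_diameters(vol)
    assert v.diameter_nm == pytest.approx(37.3, abs=H)
    assert not v.unreliable
    assert v.location == "free"
    # diameter equals brute-force voxel counting
    n = int(sphere.sum())
    assert v.diameter_nm == pytest.approx(2 * (3 * n * H**3 / (4 * np.pi)) ** (1 / 3))


def test_single_voxel_vesicle_is_flagged():
    labels = _box()
    labels[5, 5, 5] = 1000
    vol = LabelVolume(labels, VS, {1000: "vesicle"})
    (v,) = vesicle_diameters(vol)
    assert v.unreliable


def test_vesicle_location_classes(tomo_volume):
    vol, truth = tomo_volume
    measured = {v.vesicle_id: v.location for v in vesicle_diameters(vol)}
    agree = sum(1 for r in truth.tables["vesicles"] if measured[r["label"]] == r["location"])
    # boundary cases (tether gaps near the 100 nm cutoff) may flip; the vast
    # majority must agree with the planted location
    assert agree / len(truth.tables["vesicles"]) > 0.95


def _fake_link(i, ctx, length):
    return LinkMeasurement(
        link_id=i,
        context=ctx,
        length_nm=length,
        straight_length_nm=length,
        endpoint_labels=(1, 2),
        endpoint_kinds=("vesicle", "vesicle"),
        attached_both_ends=True,
    )


def test_compare_contexts_single_context_reports_means_only():
    links = [_fake_link(i, "mito-RER", 30.0 + i) for i in range(5)]
    rep = compare_contexts(links)
    assert rep["tests"] is None
    assert rep["summary"].n.item() == 5


def test_compare_contexts_type_i_error_rate():
    """With all contexts drawn from one distribution, the significant-pair
    rate stays near the nominal α."""
    rng = np.random.default_rng(0)
    sig = tot = 0
    for _ in range(150):
        links = []
        i = 0
        for ctx in ("vesicle-ribbon", "vesicle-vesicle@RER", "vesicle-RER"):
            for v in rng.normal(40.0, 8.0, 25):
                links.append(_fake_link(i, ctx, float(v)))
                i += 1
        rep = compare_contexts(links)
        sig += len(rep["shorter_pairs"])
        tot += 3
    rate = sig / tot
    assert rate < 0.08  # Games-Howell is conservative; rate ≈ α at most


def test_ribbon_links_detected_shorter(tomo_volume):
    vol, _ = tomo_volume
    links = measure_links(vol)
    rep = compare_contexts(links)
    pairs = {(a, b) for a, b, _ in rep["shorter_pairs"]}
    assert ("vesicle-vesicle@ribbon", "vesicle-vesicle@RER") in pairs
    assert ("vesicle-vesicle@ribbon", "vesicle-RER") in pairs
    assert ("vesicle-ribbon", "vesicle-vesicle@RER") in pairs
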