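"""Tomogram-scale phantom generator.

Emulates an electron-tomography field of view at 2 nm isotropic voxels:
a stack of RER cisternae (slabs) decorated with tethered mitochondria and
~37 nm membrane vesicles, and a synaptic ribbon surrounded by radial chains
of tethered vesicles.  Every tether is a rasterized straight segment whose
true surface-to-surface length is exact in nm by construction:

* ``mito-RER`` — small mitochondria held a planted gap off a cisternal face;
* ``vesicle-RER`` — single vesicles tethered to a face;
* ``vesicle-vesicle@RER`` — a face-attached vesicle with a second vesicle
  tethered behind it;
* ``vesicle-ribbon`` — vesicles tethered radially to the ribbon surface;
* ``vesicle-vesicle@ribbon`` — radial two-vesicle chains at the ribbon.

Fixed seed ⇒ bit-identical output.
"""

from __future__ import annotations

import numpy as np

from .._raster import segment_indices, sphere_indices, ellipsoid_indices
from ..io_formats import LabelVolume
from .params import GeometryInfeasibleError, TomoGenParams, gamma_from_mean_sd
from .truth import GroundTruth

__all__ = [
    "generate_tomogram_volume",
    "RER_LABEL",
    "RIBBON_LABEL",
    "TOMO_MITO_BASE",
    "VESICLE_BASE",
    "TETHER_BASE",
]

RER_LABEL = 3
RIBBON_LABEL = 4
TOMO_MITO_BASE = 100
VESICLE_BASE = 1000
TETHER_BASE = 10000

_MITO_SEMIAXES = (55.0, 80.0, 38.0)  # (x, y, z) nm; small peri-RER mitochondria
_ATTACH_GAP = 3.0  # nm, "attached" vesicle stand-off from a surface
_ROW_DZ = 80.0  # face row spacing, nm
_PITCH = {"mito-RER": 170.0, "vesicle-RER": 56.0, "vesicle-vesicle@RER": 56.0}


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0**0.5) * i
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def generate_tomogram_volume(params: TomoGenParams) -> tuple[LabelVolume, GroundTruth]:
    """Generate one tomogram phantom and its ground truth."""
    rng = np.random.default_rng(params.seed)
    h = params.voxel_size_nm
    voxel_size = (h, h, h)

    # physical layout (nm): cisternal stack in y < 860, ribbon region beyond
    ext_x, ext_y, ext_z = 760.0, 1750.0, 700.0
    shape = (int(ext_z / h), int(ext_y / h), int(ext_x / h))
    labels = np.zeros(shape, dtype=np.uint16)

    slab_half = 12.0
    slab_x = (240.0, 480.0, 720.0)
    slab_y = (40.0, 820.0)
    slab_z = (30.0, 670.0)
    ribbon_centre = np.array([380.0, 1350.0, 350.0])
    counts = {k: int(params.counts.get(k, 0)) for k in params.link_length_means}

    any_objects = any(counts.values()) or params.n_free_vesicles > 0
    ix = lambda v: int(round(v / h))  # noqa: E731

    for xs in slab_x:
        labels[
            ix(slab_z[0]) : ix(slab_z[1]) + 1,
            ix(slab_y[0]) : ix(slab_y[1]) + 1,
            ix(xs - slab_half) : ix(xs + slab_half) + 1,
        ] = RER_LABEL
    rib_idx = sphere_indices(shape, voxel_size, tuple(ribbon_centre), params.ribbon_radius_nm)
    labels[rib_idx] = RIBBON_LABEL

    links: list[dict] = []
    vesicles: list[dict] = []
    mitos: list[dict] = []
    n_vesicle = 0
    n_mito = 0

    def sample_len(ctx, n):
        m = params.link_length_means[ctx]
        s = params.link_length_sds.get(ctx, 0.0)
        return np.clip(gamma_from_mean_sd(rng, m, s, n), 4 * h, 100.0)

    def sample_diam(n, at_ribbon):
        if at_ribbon:
            m, s = params.ribbon_vesicle_diameter_mean, params.ribbon_vesicle_diameter_sd
        else:
            m, s = params.vesicle_diameter_mean, params.vesicle_diameter_sd
        return np.clip(rng.normal(m, s, size=n), 24.0, 55.0)

    def put_sphere(centre, radius, label):
        idx = sphere_indices(shape, voxel_size, tuple(centre), radius)
        free = labels[idx] == 0
        labels[idx[0][free], idx[1][free], idx[2][free]] = label
        return int(free.sum())

    def put_tether(p0, p1, label):
        """Rasterize a 1-voxel tether strictly between two surface points."""
        idx = segment_indices(shape, voxel_size, p0, p1)
        free = labels[idx] == 0
        labels[idx[0][free], idx[1][free], idx[2][free]] = label

    def add_vesicle(centre, diam, location):
        nonlocal n_vesicle
        label = VESICLE_BASE + n_vesicle
        put_sphere(centre, diam / 2.0, label)
        vesicles.append(
            {
                "id": n_vesicle,
                "label": label,
                "centre_nm": [float(v) for v in centre],
                "diameter_nm": float(diam),
                "location": location,
            }
        )
        n_vesicle += 1
        return label

    def add_link(ctx, length, label_a, label_b, p0, p1):
        label = TETHER_BASE + len(links)
        put_tether(p0, p1, label)
        links.append(
            {
                "id": len(links),
                "label": label,
                "context": ctx,
                "length_nm": float(length),
                "endpoint_labels": [int(label_a), int(label_b)],
                "p0_nm": [float(v) for v in p0],
                "p1_nm": [float(v) for v in p1],
            }
        )

    # -- cisternal-face population ------------------------------------------------
    demands = []
    for ctx in ("mito-RER", "vesicle-RER", "vesicle-vesicle@RER"):
        d_samp = sample_len(ctx, counts[ctx])
        demands.extend((ctx, float(d)) for d in d_samp)
    rng.shuffle(demands)

    rows = [
        (xs, zr)
        for xs in slab_x
        for zr in np.arange(slab_z[0] + _ROW_DZ / 2, slab_z[1] - _ROW_DZ / 2 + 1, _ROW_DZ)
    ]
    cursors = {i: slab_y[0] + 40.0 for i in range(len(rows))}
    row_order = list(range(len(rows)))
    ri = 0
    for ctx, d in demands:
        pitch = _PITCH[ctx]
        placed = False
        for _ in range(len(rows)):
            row = row_order[ri % len(rows)]
            ri += 1
            xs, zr = rows[row]
            y = cursors[row] + pitch / 2.0
            if y + pitch / 2.0 > slab_y[1] - 40.0:
                continue
            cursors[row] = y + pitch / 2.0
            face = xs - slab_half  # objects hang off the -x face
            if ctx == "mito-RER":
                nonlocal_label = TOMO_MITO_BASE + n_mito
                centre = (face - d - _MITO_SEMIAXES[0], y, zr)
                idx = ellipsoid_indices(shape, voxel_size, centre, _MITO_SEMIAXES)
                free = labels[idx] == 0
                labels[idx[0][free], idx[1][free], idx[2][free]] = nonlocal_label
                mitos.append(
                    {"id": n_mito, "label": nonlocal_label,
                     "centre_nm": [float(v) for v in centre]}
                )
                n_mito += 1
                add_link(
                    ctx, d, nonlocal_label, RER_LABEL,
                    np.array([face - d + 0.5 * h, y, zr]),
                    np.array([face - 0.5 * h, y, zr]),
                )
            elif ctx == "vesicle-RER":
                diam = sample_diam(1, at_ribbon=False)[0]
                centre = (face - d - diam / 2.0, y, zr)
                vl = add_vesicle(centre, diam, "at_RER")
                add_link(
                    ctx, d, vl, RER_LABEL,
                    np.array([face - d + 0.5 * h, y, zr]),
                    np.array([face - 0.5 * h, y, zr]),
                )
            else:  # vesicle-vesicle@RER: attached vesicle + tethered follower
                d1, d2 = sample_diam(2, at_ribbon=False)
                c1x = face - _ATTACH_GAP - d1 / 2.0
                v1 = add_vesicle((c1x, y, zr), d1, "at_RER")
                s1 = c1x - d1 / 2.0  # outer surface of the attached vesicle
                c2x = s1 - d - d2 / 2.0
                v2 = add_vesicle((c2x, y, zr), d2, "at_RER")
                add_link(
                    ctx, d, v2, v1,
                    np.array([s1 - d + 0.5 * h, y, zr]),
                    np.array([s1 - 0.5 * h, y, zr]),
                )
            placed = True
            break
        if not placed:
            raise GeometryInfeasibleError(
                f"cannot pack {ctx} site: cisternal faces exhausted "
                f"(requested counts {counts})"
            )

    # -- ribbon population ---------------------------------------------------------
    n_rib_single = counts["vesicle-ribbon"]
    n_rib_pair = counts["vesicle-vesicle@ribbon"]
    n_sites = n_rib_single + n_rib_pair
    if n_sites:
        dirs = _fibonacci_sphere(max(n_sites, 12))
        order = rng.permutation(len(dirs))[:n_sites]
        kinds = ["single"] * n_rib_single + ["pair"] * n_rib_pair
        rng.shuffle(kinds)
        d_single = sample_len("vesicle-ribbon", n_rib_single)
        d_pair = sample_len("vesicle-vesicle@ribbon", n_rib_pair)
        si = pi = 0
        R = params.ribbon_radius_nm
        for k, oi in zip(kinds, order):
            u = dirs[oi]
            if k == "single":
                d = float(d_single[si]); si += 1
                diam = sample_diam(1, at_ribbon=True)[0]
                centre = ribbon_centre + (R + d + diam / 2.0) * u
                vl = add_vesicle(centre, diam, "at_ribbon")
                add_link(
                    "vesicle-ribbon", d, vl, RIBBON_LABEL,
                    ribbon_centre + (R + d - 0.5 * h) * u,
                    ribbon_centre + (R + 0.5 * h) * u,
                )
            else:
                d = float(d_pair[pi]); pi += 1
                d1, d2 = sample_diam(2, at_ribbon=True)
                c1 = ribbon_centre + (R + _ATTACH_GAP + d1 / 2.0) * u
                v1 = add_vesicle(c1, d1, "at_ribbon")
                r1_out = R + _ATTACH_GAP + d1  # radius of v1's outer surface
                c2 = ribbon_centre + (r1_out + d + d2 / 2.0) * u
                v2 = add_vesicle(c2, d2, "at_ribbon")
                add_link(
                    "vesicle-vesicle@ribbon", d, v2, v1,
                    ribbon_centre + (r1_out + d - 0.5 * h) * u,
                    ribbon_centre + (r1_out + 0.5 * h) * u,
                )

    # -- free vesicles (buffer zone, >100 nm from every structure) -------------------
    for i in range(params.n_free_vesicles):
        diam = sample_diam(1, at_ribbon=False)[0]
        x = 120.0 + (i % 8) * 64.0
        y = 960.0 + (i // 8) * 56.0
        add_vesicle((x, y, 350.0), diam, "free")

    label_table: dict[int, str] = {}
    if (labels == RER_LABEL).any():
        label_table[RER_LABEL] = "membrane"
    if (labels == RIBBON_LABEL).any():
        label_table[RIBBON_LABEL] = "ribbon"
    label_table.update({m["label"]: "mitochondrion" for m in mitos})
    label_table.update({v["label"]: "vesicle" for v in vesicles})
    label_table.update({l["label"]: "tether" for l in links})
    volume = LabelVolume(voxels=labels, voxel_size=voxel_size, label_table=label_table)

    per_ctx = {
        ctx: {
            "n": sum(1 for l in links if l["context"] == ctx),
            "mean_length_nm": float(
                np.mean([l["length_nm"] for l in links if l["context"] == ctx])
            )
            if any(l["context"] == ctx for l in links)
            else float("nan"),
        }
        for ctx in params.link_length_means
    }
    truth = GroundTruth(
        kind="tomogram",
        params=params.to_dict(),
        tables={"links": links, "vesicles": vesicles, "mitochondria": mitos},
        summary={
            "ribbon_centre_nm": ribbon_centre.tolist(),
            "ribbon_radius_nm": params.ribbon_radius_nm,
            "per_context": per_ctx,
            "mean_diameter_at_RER_nm": float(
                np.mean([v["diameter_nm"] for v in vesicles if v["location"] == "at_RER"])
            )
            if any(v["location"] == "at_RER" for v in vesicles)
            else float("nan"),
            "mean_diameter_at_ribbon_nm": float(
                np.mean([v["diameter_nm"] for v in vesicles if v["location"] == "at_ribbon"])
            )
            if any(v["location"] == "at_ribbon" for v in vesicles)
            else float("nan"),
        },
    )
    return volume, truth
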