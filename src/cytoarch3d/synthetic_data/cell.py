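"""Cell-scale phantom generator.

Builds a flask-shaped, laterally asymmetric cell on an anisotropic
(19×19×50 nm by default) voxel grid, with complete planted ground truth:

* the cell's long axis runs along ``y`` (in-plane), the flattened/rounded
  asymmetry along ``x``, and the sectioning axis is ``z`` — matching an
  SBF-SEM acquisition in which serial sections cut across the cell's
  anterior–posterior width;
* cross-sections perpendicular to the long axis are two half-superellipses
  (flatter exponent on the flattened side), and the lateral boundary on each
  side carries a mid-cell bulge whose amplitude ratio between the rounded
  and flattened side is ``flatness_contrast``;
* membrane sheets are planted as boundary-following "curtains" on four
  concentric shells: one thin in-plane strand per section, stacked across
  sections with guaranteed pixel overlap (each section also carries the next
  section's trace, as a real surface cut by finite sections would), so the
  adjacent-section linkage rule has an exact planted truth;
* mitochondria are rounded blobs grown from seeds adjacent to a sheet with
  probability ``p_mito_association`` (otherwise seeded in the membrane-free
  sectioning fringe, well clear of every strand); growth claims free
  cytoplasm voxels until the planted per-hemisphere membrane+mitochondrion
  volume-fraction target is met exactly, to the voxel;
* synaptic ribbons sit near the basolateral membrane, each a planted
  distance (gamma around ``ribbon_type3_distance_nm``) below the basal tip
  of a dedicated Type 3 sheet, with membrane-free corridors enforced so the
  planted nearest-Type-3 distance survives;
* afferent terminals are surface boutons (spheres centred on the boundary),
  each on the flattened hemisphere with probability ``p_flat_terminal``.

Everything is generated in nm space first and rasterized second, so all
distance truths are exact in nm.  Fixed seed ⇒ bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .._raster import ellipsoid_indices, polyline_length_nm, sphere_indices
from ..io_formats import LabelVolume
from .params import CellGenParams, GeometryInfeasibleError, gamma_from_mean_sd
from .truth import GroundTruth

__all__ = [
    "generate_cell_volume",
    "CELL_LABEL",
    "NUCLEUS_LABEL",
    "SHEET_LABEL_BASE",
    "MITO_LABEL_BASE",
    "RIBBON_LABEL_BASE",
    "TERMINAL_LABEL_BASE",
]

CELL_LABEL = 1
NUCLEUS_LABEL = 2
SHEET_LABEL_BASE = 10
MITO_LABEL_BASE = 3000
RIBBON_LABEL_BASE = 5000
TERMINAL_LABEL_BASE = 6000

_FLAT_SIGN = -1  # flattened side occupies x < centre
_P_FLAT, _P_ROUND = 6.0, 4.0  # cross-section superellipse exponents per side
_BULGE_ROUND = 0.22  # rounded-side lateral bulge amplitude (fraction of half-width)
_W_CAP = 0.75  # max |z'|/C used for membrane slots
_SHELLS = {"t1": 0.30, "t2": 0.50, "t3a": 0.72, "t3b": 0.92}
_ASSOC_PITCH_NM = 19.0  # one in-plane voxel; association gap threshold scale


# ---------------------------------------------------------------------------
# analytic cell shape
# ---------------------------------------------------------------------------


@dataclass
class _Shape:
    """Analytic description of the cell in nm space."""

    H: float  # cell length along y
    a: float  # nominal lateral half-width (per side)
    c: float  # half-depth along z
    b_flat: float
    b_round: float
    y_bulge: float
    s_bulge: float
    x_mid: float  # x of the cell axis at drift phase 0
    zc: float  # z centre, nm
    drift_amp: float
    drift_period: float
    drift_phase: float
    y_nuc_basal: float
    y_nuc_centre: float
    nuc_ry: float

    def g(self, y: np.ndarray) -> np.ndarray:
        """Flask taper profile vs y (1 in the body; basal cap, neck, apex head)."""
        yf = np.clip(np.asarray(y, dtype=float) / self.H, 0.0, 1.0)
        g = np.ones_like(yf)
        rb = 0.08
        m = yf < rb
        g[m] = np.sqrt(np.clip(1.0 - ((rb - yf[m]) / rb) ** 2, 0.0025, 1.0))
        m = (yf >= 0.70) & (yf < 0.84)
        g[m] = 1.0 - 0.45 * 0.5 * (1.0 - np.cos(np.pi * (yf[m] - 0.70) / 0.14))
        m = (yf >= 0.84) & (yf < 0.88)
        g[m] = 0.55
        m = (yf >= 0.88) & (yf < 0.92)
        g[m] = 0.55 + 0.15 * 0.5 * (1.0 - np.cos(np.pi * (yf[m] - 0.88) / 0.04))
        m = yf >= 0.92
        g[m] = 0.70
        rt = 0.04
        m = yf > 1.0 - rt
        g[m] *= np.sqrt(np.clip(1.0 - ((yf[m] - (1.0 - rt)) / rt) ** 2, 0.0025, 1.0))
        return g

    def bulge(self, y: np.ndarray) -> np.ndarray:
        yv = np.asarray(y, dtype=float)
        b = np.exp(-(((yv - self.y_bulge) / self.s_bulge) ** 2))
        hi = np.clip((0.70 * self.H - yv) / (0.10 * self.H), 0.0, 1.0)
        return b * hi

    def half_width(self, y: np.ndarray, side: int) -> np.ndarray:
        """Lateral half-extent A_s(y) on side ``side`` (−1 flat, +1 round)."""
        bamp = self.b_flat if side == _FLAT_SIGN else self.b_round
        return self.a * self.g(y) * (1.0 + bamp * self.bulge(y))

    def half_depth(self, y: np.ndarray) -> np.ndarray:
        bavg = 0.5 * (self.b_flat + self.b_round)
        return self.c * self.g(y) * (1.0 + bavg * self.bulge(y))

    def exponent(self, side: int) -> float:
        return _P_FLAT if side == _FLAT_SIGN else _P_ROUND

    def x_axis(self, z_nm: float | np.ndarray) -> float | np.ndarray:
        """x position of the (drifting) cell axis at section depth z."""
        return self.x_mid + self.drift_amp * np.sin(
            2.0 * np.pi * (np.asarray(z_nm, dtype=float) - self.zc) / self.drift_period
            + self.drift_phase
        )

    def lateral_extent(self, y: np.ndarray, z_nm: float, side: int) -> np.ndarray:
        """In-plane |x - axis| of the boundary at height y, section depth z."""
        p = self.exponent(side)
        C = self.half_depth(y)
        w = np.abs(z_nm - self.zc) / np.maximum(C, 1e-9)
        t = np.clip(1.0 - w**p, 0.0, 1.0) ** (1.0 / p)
        return self.half_width(y, side) * t

    def surface_radius(self, y: float, phi: float, side: int) -> float:
        """Cross-section boundary radius at polar angle phi in the (x, z) plane."""
        p = self.exponent(side)
        A = float(self.half_width(np.array([y]), side)[0])
        C = float(self.half_depth(np.array([y]))[0])
        cp, sp = abs(np.cos(phi)), abs(np.sin(phi))
        return ((cp / A) ** p + (sp / C) ** p) ** (-1.0 / p)


# ---------------------------------------------------------------------------
# generator
# ---------------------------------------------------------------------------


def generate_cell_volume(params: CellGenParams) -> tuple[LabelVolume, GroundTruth]:
    """Generate one cell phantom and its ground truth.

    Raises :class:`GeometryInfeasibleError` naming the violated constraint if
    the requested objects cannot be packed (e.g. membrane fractions beyond
    what the geometry can host).
    """
    rng = np.random.default_rng(params.seed)
    sx, sy, sz = params.voxel_size

    H = params.cell_height_um * 1000.0
    a = params.cell_width_um * 1000.0 / 2.0
    c = params.depth_um * 1000.0 / 2.0
    b_r = _BULGE_ROUND
    b_f = b_r / params.flatness_contrast

    r_t = params.terminal_radius_nm
    x_margin = r_t + 4 * sx
    z_margin = r_t + 4 * sz
    y_margin = 6 * sy
    A_max = a * (1 + max(b_f, b_r))
    nx = int(np.ceil((2 * A_max + 2 * x_margin) / sx)) + 1
    ny = int(np.ceil((H + 2 * y_margin) / sy)) + 1
    nz = int(np.ceil((2 * c * (1 + 0.5 * (b_f + b_r)) + 2 * z_margin) / sz)) + 1

    shape = _Shape(
        H=H,
        a=a,
        c=c,
        b_flat=b_f,
        b_round=b_r,
        y_bulge=0.40 * H,
        s_bulge=0.18 * H,
        x_mid=nx * sx / 2.0,
        zc=nz * sz / 2.0,
        drift_amp=0.05 * a,
        drift_period=max(nz * sz, 1.0),
        drift_phase=float(rng.uniform(0, 2 * np.pi)),
        y_nuc_basal=params.infranuclear_fraction * H,
        y_nuc_centre=params.infranuclear_fraction * H + 0.15 * H,
        nuc_ry=0.15 * H,
    )
    y_off = y_margin  # cell base sits at y = y_off in volume coordinates

    labels = np.zeros((nz, ny, nx), dtype=np.uint16)
    x_nm = np.arange(nx) * sx
    y_nm = np.arange(ny) * sy
    y_cell = y_nm - y_off  # cell-frame y (0 at base)

    in_cell_y = (y_cell >= 0) & (y_cell <= H)
    yc = np.clip(y_cell, 0, H)
    A_f_rows = shape.half_width(yc, _FLAT_SIGN)
    A_r_rows = shape.half_width(yc, +1)
    C_rows = np.maximum(shape.half_depth(yc), 1e-9)

    cx_truth = np.full(nz, np.nan)
    cy_truth = np.full(nz, np.nan)
    for iz in range(nz):
        z = iz * sz
        w = abs(z - shape.zc) / C_rows
        rows = in_cell_y & (w < 1.0)
        if not rows.any():
            continue
        x0z = float(shape.x_axis(z))
        u = x_nm - x0z
        tf = np.zeros(ny)
        tr = np.zeros(ny)
        tf[rows] = np.clip(1.0 - w[rows] ** _P_FLAT, 0.0, 1.0) ** (1.0 / _P_FLAT)
        tr[rows] = np.clip(1.0 - w[rows] ** _P_ROUND, 0.0, 1.0) ** (1.0 / _P_ROUND)
        xf = A_f_rows * tf
        xr = A_r_rows * tr
        neg = u < 0
        sec = np.where(neg[None, :], (-u)[None, :] <= xf[:, None], u[None, :] <= xr[:, None])
        sec &= rows[:, None]
        if sec.any():
            labels[iz][sec] = CELL_LABEL
            ys, xs = np.nonzero(sec)
            cx_truth[iz] = float(xs.mean() * sx)
            cy_truth[iz] = float(ys.mean() * sy)

    if not (labels == CELL_LABEL).any():
        raise GeometryInfeasibleError("cell mask empty: cell dimensions below voxel size")

    nuc_idx = ellipsoid_indices(
        labels.shape,
        params.voxel_size,
        (shape.x_mid, shape.y_nuc_centre + y_off, shape.zc),
        (0.55 * a, shape.nuc_ry, 0.55 * c),
    )
    keep = labels[nuc_idx] == CELL_LABEL
    labels[nuc_idx[0][keep], nuc_idx[1][keep], nuc_idx[2][keep]] = NUCLEUS_LABEL

    builder = _OrganelleBuilder(params, shape, labels, rng, y_off)
    builder.build()

    label_table: dict[int, str] = {CELL_LABEL: "cell", NUCLEUS_LABEL: "nucleus"}
    label_table.update({s["label"]: "membrane" for s in builder.sheets})
    label_table.update({m["label"]: "mitochondrion" for m in builder.mitos})
    label_table.update({r["label"]: "ribbon" for r in builder.ribbons})
    label_table.update({t["label"]: "terminal" for t in builder.terminals})
    volume = LabelVolume(voxels=labels, voxel_size=params.voxel_size, label_table=label_table)

    truth = GroundTruth(
        kind="cell",
        params=params.to_dict(),
        tables={
            "centre_line": [
                {"z_index": iz, "cx_nm": cx_truth[iz], "cy_nm": cy_truth[iz]}
                for iz in range(nz)
                if np.isfinite(cx_truth[iz])
            ],
            "sheets": builder.sheets,
            "mitochondria": builder.mitos,
            "ribbons": builder.ribbons,
            "terminals": builder.terminals,
        },
        summary={
            "flat_side_sign": _FLAT_SIGN,
            "flat_faces": builder.flat_faces,
            "y_base_nm": y_off,
            "y_nucleus_basal_nm": shape.y_nuc_basal + y_off,
            "nucleus_centre_nm": [shape.x_mid, shape.y_nuc_centre + y_off, shape.zc],
            "neck_y_nm": 0.86 * H + y_off,
            "fraction_axis": builder.fraction_axis,
            "hemisphere_fractions": builder.fraction_truth,
            "hemisphere_cell_voxels": builder.cell_voxel_counts,
            "association_fraction": builder.association_fraction,
            "n_sheets_by_type": builder.n_sheets_by_type,
            "area_by_type_um2": builder.area_by_type,
            "flatness_bands": builder.flatness_truth,
        },
    )
    return volume, truth


# ---------------------------------------------------------------------------
# organelle packing
# ---------------------------------------------------------------------------


class _OrganelleBuilder:
    def __init__(self, params: CellGenParams, shape: _Shape, labels: np.ndarray, rng, y_off):
        self.p = params
        self.shape = shape
        self.labels = labels
        self.rng = rng
        self.y_off = y_off
        self.sx, self.sy, self.sz = params.voxel_size
        self.nz, self.ny, self.nx = labels.shape
        self.sheets: list[dict] = []
        self.mitos: list[dict] = []
        self.ribbons: list[dict] = []
        self.terminals: list[dict] = []
        self.fraction_truth: dict = {}
        self.fraction_axis = None
        self.cell_voxel_counts: dict = {}
        self.association_fraction = float("nan")
        self.n_sheets_by_type: dict = {}
        self.area_by_type: dict = {}
        self.flatness_truth: list[dict] = []
        self.flat_faces = "modiolar" if rng.random() < 0.5 else "pillar"
        H = shape.H
        self.y_lo = 0.09 * H
        self.y_hi = shape.y_nuc_basal - 100.0
        self.t3_len = max(0.035 * H, 8 * self.sy)
        self.t3_zhalf = 3  # sections
        zc_idx = shape.zc / self.sz
        z_use = _W_CAP * shape.c / self.sz
        self.iz_lo = int(np.ceil(zc_idx - z_use))
        self.iz_hi = int(np.floor(zc_idx + z_use))
        self._centre_cache: dict[int, float] = {}

    # -- helpers ---------------------------------------------------------------

    def _trace(self, side: int, inset: float, y0: float, y1: float, iz: int):
        """Strand polyline (x, y) in volume nm at section iz (cell-frame y0..y1)."""
        ys = np.arange(y0, y1, 0.5 * self.sy)
        if len(ys) < 2:
            ys = np.array([y0, y1])
        X = self.shape.lateral_extent(ys, iz * self.sz, side)
        x = self.shape.x_axis(iz * self.sz) + side * inset * X
        return np.column_stack([x, ys + self.y_off])

    def _raster_trace(self, pts):
        ix = np.rint(pts[:, 0] / self.sx).astype(np.int64)
        iy = np.rint(pts[:, 1] / self.sy).astype(np.int64)
        ok = (ix >= 0) & (ix < self.nx) & (iy >= 0) & (iy < self.ny)
        flat = np.unique(iy[ok] * self.nx + ix[ok])
        return flat // self.nx, flat % self.nx

    def _centroid_x(self, iz: int) -> float:
        if iz not in self._centre_cache:
            sec = (self.labels[iz] != 0) & (self.labels[iz] < TERMINAL_LABEL_BASE)
            xs = np.nonzero(sec)[1]
            self._centre_cache[iz] = float(xs.mean() * self.sx) if len(xs) else np.nan
        return self._centre_cache[iz]

    def _hemi_of_x(self, iz: int, x_nm: np.ndarray) -> np.ndarray:
        """True where x lies on the flattened side of the section centroid."""
        cx = self._centroid_x(iz)
        return (np.asarray(x_nm, dtype=float) - cx) * _FLAT_SIGN > 0

    # -- build sequence ----------------------------------------------------------

    def build(self):
        counts = self.p.sheet_area_mixture.counts
        self._place_ribbons()
        self._plan_and_place_sheets(counts)
        self._place_mitochondria_and_balance()
        self._place_terminals()
        self._finalize_truth()

    # -- ribbons -----------------------------------------------------------------

    def _place_ribbons(self):
        n = self.p.n_ribbons
        self.ribbon_sites = []  # (iz, side, y_rib_cell, d_i)
        self.partner_extents = []  # (side, y0, y1, iz0, iz1)
        if n == 0:
            return
        if self.p.sheet_area_mixture.counts[2] < n:
            raise GeometryInfeasibleError(
                "n_ribbons exceeds planted Type 3 sheet count: each ribbon needs a "
                "dedicated Type 3 partner sheet"
            )
        q = _SHELLS["t3b"]
        per_side = {_FLAT_SIGN: n - n // 2, -_FLAT_SIGN: n // 2}
        d_lo = self.p.ribbon_radius_nm + 80.0
        d_hi = self.y_hi - self.y_lo - self.t3_len - 300.0
        if d_hi <= d_lo:
            raise GeometryInfeasibleError(
                "ribbon_type3_distance does not fit: infranuclear membrane zone too short"
            )
        d_all = np.clip(
            gamma_from_mean_sd(
                self.rng, self.p.ribbon_type3_distance_nm, self.p.ribbon_type3_distance_sd_nm, n
            ),
            d_lo,
            d_hi,
        )
        k = 0
        for side in (_FLAT_SIGN, -_FLAT_SIGN):
            m = per_side[side]
            if m == 0:
                continue
            z_positions = np.linspace(self.iz_lo + 5, self.iz_hi - 5, m)
            for zp in z_positions:
                iz = int(round(zp))
                y_rib = self.y_lo + 120.0
                d_i = float(d_all[k])
                k += 1
                pts = self._trace(side, q, y_rib, y_rib + self.sy, iz)
                centre = (float(pts[0, 0]), y_rib + self.y_off, iz * self.sz)
                idx = sphere_indices(
                    self.labels.shape, self.p.voxel_size, centre, self.p.ribbon_radius_nm
                )
                ok = self.labels[idx] == CELL_LABEL
                label = RIBBON_LABEL_BASE + len(self.ribbons)
                self.labels[idx[0][ok], idx[1][ok], idx[2][ok]] = label
                self.ribbons.append(
                    {
                        "id": len(self.ribbons),
                        "label": label,
                        "centre_nm": list(centre),
                        "side": "flat" if side == _FLAT_SIGN else "round",
                        "planted_t3_distance_nm": d_i,
                        "partner_sheet_label": None,
                    }
                )
                self.ribbon_sites.append((iz, side, y_rib, d_i))
                self.partner_extents.append(
                    (side, y_rib + d_i, y_rib + d_i + self.t3_len,
                     iz - self.t3_zhalf, iz + self.t3_zhalf)
                )

    # -- sheets ------------------------------------------------------------------

    def _plan_and_place_sheets(self, counts):
        n1, n2, n3 = counts
        plan = []  # (type, side, inset, y0, y1, iz0, iz1, partner_ribbon or None)
        ff, fr = self.p.membrane_fraction_flat, self.p.membrane_fraction_round
        w_flat = 0.5 if ff is None or fr is None else ff / (ff + fr)

        def side_split(count):
            nf = int(round(count * w_flat))
            return {_FLAT_SIGN: nf, -_FLAT_SIGN: count - nf}

        z_mid = (self.iz_lo + self.iz_hi) // 2
        z_span = self.iz_hi - self.iz_lo

        for side, m in side_split(n1).items():  # Type 1: full-zone curtains
            for j in range(m):
                half = max(8, int(0.40 * z_span))
                zcen = z_mid + int((j - (m - 1) / 2.0) * 0.12 * z_span)
                plan.append(
                    (1, side, _SHELLS["t1"] + 0.05 * j, self.y_lo, self.y_hi,
                     zcen - half, zcen + half, None)
                )
        for side, m in side_split(n2).items():  # Type 2: half-length curtains
            for j in range(m):
                span_y = self.y_hi - self.y_lo
                y0 = self.y_lo + (0.52 * span_y if j % 2 else 0.06 * span_y)
                y1 = y0 + 0.40 * span_y
                half = max(5, int(0.16 * z_span))
                frac = j / max(1, m - 1) if m > 1 else 0.5
                zcen = self.iz_lo + int((0.2 + 0.6 * frac) * z_span)
                plan.append((2, side, _SHELLS["t2"] + 0.05 * (j % 2), y0, y1,
                             zcen - half, zcen + half, None))

        t3_sites = []
        for ridx, (iz_r, side, y_rib, d_i) in enumerate(self.ribbon_sites):
            y0 = y_rib + d_i
            t3_sites.append((3, side, _SHELLS["t3b"], y0, y0 + self.t3_len,
                             iz_r - self.t3_zhalf, iz_r + self.t3_zhalf, ridx))
        n3_grid = n3 - len(t3_sites)
        if n3_grid < 0:
            raise GeometryInfeasibleError("Type 3 count below ribbon partner requirement")

        grid_slots = self._t3_grid_slots()
        if len(grid_slots) < n3_grid:
            raise GeometryInfeasibleError(
                f"cannot pack {n3_grid} grid Type 3 sheets: only {len(grid_slots)} "
                "membrane slots available in this cell geometry"
            )
        order = self.rng.permutation(len(grid_slots))
        chosen = [grid_slots[i] for i in order[:n3_grid]]
        t3_sites.extend((3, s, q, y0, y1, iz0, iz1, None) for (s, q, y0, y1, iz0, iz1) in chosen)
        plan.extend(t3_sites)

        for stype, side, q, y0, y1, iz0, iz1, ridx in plan:
            label = SHEET_LABEL_BASE + len(self.sheets)
            iz0 = max(iz0, self.iz_lo - 1)
            iz1 = min(iz1, self.iz_hi + 1)
            lengths = []
            voxels = 0
            traces = {iz: self._trace(side, q, y0, y1, iz) for iz in range(iz0, iz1 + 1)}
            for iz in range(iz0, iz1 + 1):
                pts = traces[iz]
                iy, ix = self._raster_trace(pts)
                if iz + 1 in traces:  # bridge to the next section: guaranteed overlap
                    iy2, ix2 = self._raster_trace(traces[iz + 1])
                    iy = np.concatenate([iy, iy2])
                    ix = np.concatenate([ix, ix2])
                # strands are 3 voxels thick in-plane (tube-scale membrane profile)
                iy = np.concatenate([iy, iy, iy])
                ix = np.concatenate([ix - 1, ix, ix + 1])
                ok = (ix >= 0) & (ix < self.nx)
                flat = np.unique(iy[ok] * self.nx + ix[ok])
                iy, ix = flat // self.nx, flat % self.nx
                ok = self.labels[iz, iy, ix] == CELL_LABEL
                self.labels[iz, iy[ok], ix[ok]] = label
                voxels += int(ok.sum())
                lengths.append(polyline_length_nm(pts))
            self.sheets.append(
                {
                    "id": len(self.sheets),
                    "label": label,
                    "type": stype,
                    "side": "flat" if side == _FLAT_SIGN else "round",
                    "side_sign": side,
                    "inset": q,
                    "z_extent": [iz0, iz1],
                    "y0_nm": y0 + self.y_off,
                    "y1_nm": y1 + self.y_off,
                    "area_face_um2": float(np.sum(lengths) * self.sz / 1e6),
                    "n_strands": iz1 - iz0 + 1,
                    "voxels": voxels,
                }
            )
            if ridx is not None:
                self.ribbons[ridx]["partner_sheet_label"] = label
        self.n_sheets_by_type = {
            t: sum(1 for s in self.sheets if s["type"] == t) for t in (1, 2, 3)
        }
        self.area_by_type = {
            t: float(sum(s["area_face_um2"] for s in self.sheets if s["type"] == t))
            for t in (1, 2, 3)
        }

    def _t3_grid_slots(self):
        """Candidate Type 3 slots clear of ribbon corridors and partner sheets."""
        slots = []
        y_step = self.t3_len + 0.10 * 1000.0
        z_step = 2 * self.t3_zhalf + 2
        for side in (_FLAT_SIGN, -_FLAT_SIGN):
            for q in (_SHELLS["t3a"], _SHELLS["t3b"]):
                y0 = self.y_lo
                while y0 + self.t3_len <= self.y_hi:
                    iz0 = self.iz_lo
                    while iz0 + 2 * self.t3_zhalf <= self.iz_hi:
                        iz1 = iz0 + 2 * self.t3_zhalf
                        if self._slot_clear(side, q, y0, y0 + self.t3_len, iz0, iz1):
                            slots.append((side, q, y0, y0 + self.t3_len, iz0, iz1))
                        iz0 += z_step
                    y0 += y_step
        return slots

    def _slot_clear(self, side, q, y0, y1, iz0, iz1) -> bool:
        if not self.ribbon_sites:
            return True
        # never touch a partner sheet on the same shell
        if q == _SHELLS["t3b"]:
            for pside, py0, py1, piz0, piz1 in self.partner_extents:
                if pside != side:
                    continue
                if iz0 <= piz1 + 1 and iz1 >= piz0 - 1 and y0 <= py1 + 100 and y1 >= py0 - 100:
                    return False
        parts = []
        for iz in (iz0, (iz0 + iz1) // 2, iz1):
            p = self._trace(side, q, y0, y1, iz)
            parts.append(np.column_stack([p, np.full(len(p), iz * self.sz)]))
        xyz = np.concatenate(parts)
        for (iz_r, r_side, y_rib, d_i), rec in zip(self.ribbon_sites, self.ribbons):
            centre = np.asarray(rec["centre_nm"])
            dmin = np.sqrt(((xyz - centre[None, :]) ** 2).sum(axis=1)).min()
            if dmin < d_i + 80.0:
                return False
        return True

    # -- mitochondria + membrane-fraction balancing --------------------------------

    def _hemisphere_axis(self):
        if self.p.membrane_fraction_anterior is not None:
            return "ant_post", {
                "anterior": self.p.membrane_fraction_anterior,
                "posterior": self.p.membrane_fraction_posterior,
            }
        if self.p.membrane_fraction_flat is not None:
            return "flat_round", {
                "flat": self.p.membrane_fraction_flat,
                "round": self.p.membrane_fraction_round,
            }
        return None, {}

    def _voxel_hemi(self, iz: int, ix: np.ndarray, axis: str, z_mid_idx: int) -> np.ndarray:
        if axis == "flat_round":
            return self._hemi_of_x(iz, np.asarray(ix) * self.sx)
        return np.full(np.atleast_1d(ix).shape, iz <= z_mid_idx)

    def _count_region(self, axis, z_mid_idx):
        """(cell_voxels, hit_voxels) per hemisphere over the infranuclear zone."""
        y_cut = int(np.floor((self.shape.y_nuc_basal + self.y_off) / self.sy))
        mem_lo, mem_hi = SHEET_LABEL_BASE, SHEET_LABEL_BASE + max(1, len(self.sheets))
        mito_lo, mito_hi = MITO_LABEL_BASE, MITO_LABEL_BASE + max(1, len(self.mitos))
        cells = {True: 0, False: 0}
        hits = {True: 0, False: 0}
        for iz in range(self.nz):
            sec = self.labels[iz, :y_cut, :]
            inc = (sec != 0) & (sec < TERMINAL_LABEL_BASE)
            if not inc.any():
                continue
            hit = ((sec >= mem_lo) & (sec < mem_hi)) | ((sec >= mito_lo) & (sec < mito_hi))
            ys, xs = np.nonzero(inc)
            hemi = self._voxel_hemi(iz, xs, axis, z_mid_idx)
            hvals = hit[ys, xs]
            n1 = int(hemi.sum())
            cells[True] += n1
            cells[False] += len(xs) - n1
            hits[True] += int(hvals[hemi].sum())
            hits[False] += int(hvals[~hemi].sum())
        return cells, hits

    def _z_mid_idx(self) -> int:
        zs = np.nonzero((self.labels != 0).any(axis=(1, 2)))[0]
        return int((zs.min() + zs.max()) // 2)

    def _assoc_seed_pool(self):
        """Membrane-adjacent free voxels: (iz, iy, ix, sheet_idx)."""
        out = []
        for si, s in enumerate(self.sheets):
            iz0, iz1 = s["z_extent"]
            side = s["side_sign"]
            y0 = s["y0_nm"] - self.y_off
            y1 = s["y1_nm"] - self.y_off
            for iz in range(max(iz0 + 1, 0), min(iz1, self.nz), 4):
                pts = self._trace(side, s["inset"], y0, y1, iz)
                iy, ix = self._raster_trace(pts)
                step = max(1, int(400.0 / self.sy))
                for k in range(0, len(iy), step):
                    for dirn in (1, -1):
                        ix2 = int(ix[k] - side * dirn * 2)
                        if 0 <= ix2 < self.nx and self.labels[iz, iy[k], ix2] == CELL_LABEL:
                            out.append((iz, int(iy[k]), ix2, si))
        return out

    def _free_seed_pool(self, near_mem):
        """Seeds in the sectioning fringe, clear of all membranes."""
        out = []
        y_span = np.arange(self.y_lo + 300.0, self.y_hi - 300.0, 600.0)
        for side in (_FLAT_SIGN, -_FLAT_SIGN):
            for zsign in (+1, -1):
                for wpos in (0.85, 0.91):
                    for inset in (0.3, 0.5, 0.65):
                        for y in y_span:
                            C = float(self.shape.half_depth(np.array([y]))[0])
                            iz = int(round((self.shape.zc + zsign * wpos * C) / self.sz))
                            if not 0 <= iz < self.nz:
                                continue
                            A = float(
                                self.shape.lateral_extent(np.array([y]), iz * self.sz, side)[0]
                            )
                            ix = int(
                                round(
                                    (float(self.shape.x_axis(iz * self.sz)) + side * inset * A)
                                    / self.sx
                                )
                            )
                            iy = int(round((y + self.y_off) / self.sy))
                            if not (0 <= ix < self.nx and 0 <= iy < self.ny):
                                continue
                            if self.labels[iz, iy, ix] == CELL_LABEL and not near_mem[iz, iy, ix]:
                                out.append((iz, iy, ix, side, zsign))
        return out

    def _membrane_proximity_mask(self, radius_vox: int = 3):
        """Voxels within ``radius_vox`` in-plane pixels (1 section) of membrane."""
        from scipy import ndimage

        mem = (self.labels >= SHEET_LABEL_BASE) & (
            self.labels < SHEET_LABEL_BASE + max(1, len(self.sheets))
        )
        st = np.zeros((3, 2 * radius_vox + 1, 2 * radius_vox + 1), dtype=bool)
        yy, xx = np.mgrid[-radius_vox : radius_vox + 1, -radius_vox : radius_vox + 1]
        disk = (yy**2 + xx**2) <= radius_vox**2
        st[0] = st[1] = st[2] = disk
        return ndimage.binary_dilation(mem, structure=st)

    def _place_mitochondria_and_balance(self):
        axis, targets = self._hemisphere_axis()
        z_mid_idx = self._z_mid_idx()
        hemi_names = (
            ("flat", "round") if axis in (None, "flat_round") else ("anterior", "posterior")
        )
        self.fraction_axis = axis
        cells, hits = self._count_region(axis or "flat_round", z_mid_idx)
        name_of = {True: hemi_names[0], False: hemi_names[1]}
        self.cell_voxel_counts = {name_of[h]: cells[h] for h in (True, False)}

        v_nom = 4200  # nominal blob volume, voxels (~0.45 x 0.45 x 0.9 um mito)
        if axis is None:
            need = {h: int(hits[h]) for h in (True, False)}
        else:
            need = {}
            for h in (True, False):
                budget = int(round(targets[name_of[h]] * cells[h]))
                n = budget - hits[h]
                if n < 0:
                    raise GeometryInfeasibleError(
                        f"membrane fraction target {targets[name_of[h]]} for hemisphere "
                        f"{name_of[h]} is below the planted membrane load"
                    )
                need[h] = n

        near_mem = self._membrane_proximity_mask()
        assoc_pool = self._assoc_seed_pool()
        free_pool = self._free_seed_pool(near_mem)
        self.rng.shuffle(assoc_pool)
        self.rng.shuffle(free_pool)
        if axis == "ant_post":
            hemi_of_assoc = lambda s: s[0] <= z_mid_idx  # noqa: E731
            hemi_of_free = lambda s: s[0] <= z_mid_idx  # noqa: E731
        else:
            hemi_of_assoc = lambda s: self.sheets[s[3]]["side_sign"] == _FLAT_SIGN  # noqa: E731
            hemi_of_free = lambda s: s[3] == _FLAT_SIGN  # noqa: E731

        cx_arr = np.array([self._centroid_x(iz) for iz in range(self.nz)])
        y_cut = int(np.floor((self.shape.y_nuc_basal + self.y_off) / self.sy))
        blob_cap = int(2.2 * v_nom)
        remaining = dict(need)
        blobs = []  # dicts with frontier arrays
        ai = fi = 0

        def spawn(h, assoc):
            nonlocal ai, fi
            pool, hemi_fn = (assoc_pool, hemi_of_assoc) if assoc else (free_pool, hemi_of_free)
            i = ai if assoc else fi
            while i < len(pool):
                seed = pool[i]
                i += 1
                if hemi_fn(seed) != h:
                    continue
                iz, iy, ix = seed[0], seed[1], seed[2]
                if self.labels[iz, iy, ix] != CELL_LABEL:
                    continue
                if assoc:
                    ai = i
                else:
                    fi = i
                label = MITO_LABEL_BASE + len(self.mitos)
                self.labels[iz, iy, ix] = label
                remaining[h] -= 1
                anchor = self.sheets[seed[3]] if assoc else None
                self.mitos.append(
                    {
                        "id": len(self.mitos),
                        "label": label,
                        "seed_zyx": [iz, iy, ix],
                        "associated": bool(assoc),
                        "anchor_sheet_label": None if anchor is None else anchor["label"],
                        "anchor_type": None if anchor is None else anchor["type"],
                        "hemisphere": name_of[h],
                        "voxels": 1,
                    }
                )
                blobs.append(
                    {
                        "idx": len(self.mitos) - 1,
                        "h": h,
                        "assoc": bool(assoc),
                        "front": (
                            np.array([iz]),
                            np.array([iy]),
                            np.array([ix]),
                        ),
                        "active": True,
                    }
                )
                return True
            if assoc:
                ai = i
            else:
                fi = i
            return False

        for wave in range(12):
            if all(v <= 0 for v in remaining.values()):
                break
            spawned = 0
            for h in (True, False):
                k = int(np.ceil(max(remaining[h], 0) / v_nom))
                for _ in range(k):
                    if remaining[h] <= 0:
                        break
                    assoc = bool(self.rng.random() < self.p.p_mito_association)
                    ok = spawn(h, assoc) or spawn(h, not assoc)
                    spawned += int(ok)
            if spawned == 0 and any(v > 0 for v in remaining.values()):
                break
            for r in range(16):
                grew = False
                for b in blobs:
                    if not b["active"] or remaining[b["h"]] <= 0:
                        continue
                    rec = self.mitos[b["idx"]]
                    if rec["voxels"] >= blob_cap:
                        b["active"] = False
                        continue
                    fz, fy, fx = b["front"]
                    offs = [(0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
                    if r % 3 == 2:
                        offs += [(1, 0, 0), (-1, 0, 0)]
                    cz = np.concatenate([fz + o[0] for o in offs])
                    cy = np.concatenate([fy + o[1] for o in offs])
                    cx_ = np.concatenate([fx + o[2] for o in offs])
                    ok = (
                        (cz >= 0)
                        & (cz < self.nz)
                        & (cy >= 0)
                        & (cy < y_cut)  # mitochondria stay infranuclear
                        & (cx_ >= 0)
                        & (cx_ < self.nx)
                    )
                    cz, cy, cx_ = cz[ok], cy[ok], cx_[ok]
                    flat = np.unique(cz * (self.ny * self.nx) + cy * self.nx + cx_)
                    cz = flat // (self.ny * self.nx)
                    cy = (flat // self.nx) % self.ny
                    cx_ = flat % self.nx
                    ok = self.labels[cz, cy, cx_] == CELL_LABEL
                    cz, cy, cx_ = cz[ok], cy[ok], cx_[ok]
                    if b["assoc"] is False and len(cz):
                        ok = ~near_mem[cz, cy, cx_]
                        cz, cy, cx_ = cz[ok], cy[ok], cx_[ok]
                    if len(cz):
                        if axis == "ant_post":
                            hemi = cz <= z_mid_idx
                        else:
                            hemi = (cx_ * self.sx - cx_arr[cz]) * _FLAT_SIGN > 0
                        ok = hemi == b["h"]
                        cz, cy, cx_ = cz[ok], cy[ok], cx_[ok]
                    take = min(len(cz), remaining[b["h"]], blob_cap - rec["voxels"])
                    if take <= 0:
                        if len(cz) == 0:
                            b["active"] = False
                        continue
                    cz, cy, cx_ = cz[:take], cy[:take], cx_[:take]
                    self.labels[cz, cy, cx_] = rec["label"]
                    rec["voxels"] += take
                    remaining[b["h"]] -= take
                    b["front"] = (cz, cy, cx_)
                    grew = True
                if not grew:
                    break

        if axis is not None:
            worst = max(remaining.values())
            if worst > max(64, int(0.0008 * min(cells.values()))):
                raise GeometryInfeasibleError(
                    "membrane fraction targets unreachable: mitochondrion growth "
                    f"jammed with voxel deficits "
                    f"{ {name_of[h]: remaining[h] for h in remaining} }"
                )
        if self.mitos:
            self.association_fraction = float(np.mean([m["associated"] for m in self.mitos]))
        cells2, hits2 = self._count_region(axis or "flat_round", z_mid_idx)
        self.fraction_truth = {
            name_of[h]: hits2[h] / cells2[h] if cells2[h] else float("nan")
            for h in (True, False)
        }

    # -- terminals -----------------------------------------------------------------

    def _place_terminals(self):
        n = self.p.n_terminals
        if n == 0:
            return
        r_t = self.p.terminal_radius_nm
        H = self.shape.H
        y_min, y_max = 0.05 * H, 0.37 * H
        phis = np.deg2rad([-60, -40, -20, 0, 20, 40, 60])
        n_levels = max(2, int((y_max - y_min) / (2.4 * r_t)))
        capacity = len(phis) * n_levels
        dy = (y_max - y_min) / n_levels
        side_count = {_FLAT_SIGN: 0, -_FLAT_SIGN: 0}
        draws = self.rng.random(n)
        for i in range(n):
            side = _FLAT_SIGN if draws[i] < self.p.p_flat_terminal else -_FLAT_SIGN
            k = side_count[side]
            if k >= capacity:
                raise GeometryInfeasibleError(
                    f"n_terminals={n}: more than {capacity} boutons drawn on one side "
                    "cannot be packed on this cell surface"
                )
            side_count[side] += 1
            phi = float(phis[k % len(phis)])
            y = y_min + (k // len(phis) + 0.5) * dy
            r = self.shape.surface_radius(y, phi, side)
            czn = self.shape.zc + r * np.sin(phi)
            cxs = float(self.shape.x_axis(czn)) + side * r * np.cos(phi)
            centre = (cxs, y + self.y_off, czn)
            idx = sphere_indices(self.labels.shape, self.p.voxel_size, centre, r_t)
            ok = self.labels[idx] == 0
            label = TERMINAL_LABEL_BASE + len(self.terminals)
            self.labels[idx[0][ok], idx[1][ok], idx[2][ok]] = label
            self.terminals.append(
                {
                    "id": len(self.terminals),
                    "label": label,
                    "centre_nm": [float(v) for v in centre],
                    "hemisphere": "flat" if side == _FLAT_SIGN else "round",
                    "side_sign": side,
                    "y_from_base_nm": float(y),
                    "phi_deg": float(np.rad2deg(phi)),
                }
            )

    # -- post-hoc truth ---------------------------------------------------------------

    def _finalize_truth(self):
        trees = {}
        if self.sheets:
            for t in (1, 2, 3):
                labs = [s["label"] for s in self.sheets if s["type"] == t]
                if not labs:
                    continue
                mask = np.isin(self.labels, labs)
                zz, yy, xx = np.nonzero(mask)
                if len(zz):
                    trees[t] = cKDTree(
                        np.column_stack([xx * self.sx, yy * self.sy, zz * self.sz])
                    )
        for rec in self.ribbons:
            centre = np.asarray(rec["centre_nm"])
            dists = {}
            for t, tree in trees.items():
                d, _ = tree.query(centre)
                dists[f"type{t}"] = float(d)
            rec["nearest_sheet_distance_nm"] = dists
            if dists:
                rec["nearest_type"] = int(min(dists, key=dists.get).removeprefix("type"))
        # measured per-mitochondrion minimal gap per type (local crops; exact)
        if self.mitos:
            lo, hi = MITO_LABEL_BASE, MITO_LABEL_BASE + len(self.mitos)
            zz, yy, xx = np.nonzero((self.labels >= lo) & (self.labels < hi))
            vals = self.labels[zz, yy, xx]
            order = np.argsort(vals, kind="stable")
            zz, yy, xx, vals = zz[order], yy[order], xx[order], vals[order]
            bounds = np.searchsorted(vals, np.arange(lo, hi + 1))
            all_xyz = np.column_stack([xx * self.sx, yy * self.sy, zz * self.sz])
            dmins = {
                t: tree.query(all_xyz, workers=1)[0] for t, tree in trees.items()
            }
            for m in self.mitos:
                j0, j1 = bounds[m["label"] - lo], bounds[m["label"] - lo + 1]
                m["centre_nm"] = [float(v) for v in all_xyz[j0:j1].mean(axis=0)]
                gaps = {
                    int(t): float(max(0.0, d[j0:j1].min() - _ASSOC_PITCH_NM))
                    for t, d in dmins.items()
                }
                m["gap_by_type_nm"] = gaps
                touched = sorted(t for t, g in gaps.items() if g <= _ASSOC_PITCH_NM)
                m["types_touched"] = touched
                m["n_types_touched"] = len(touched)
        # analytic flatness truth per depth band below the neck; tangent per side
        # touches the maximal lateral extent over the band union
        H = self.shape.H
        y_neck = 0.86 * H
        bands_um = [(1.0, 4.0), (5.0, 7.0), (7.0, 11.0)]
        bands_nm = [
            (y_neck - hi * 1000.0, y_neck - lo * 1000.0)
            for lo, hi in bands_um
            if y_neck - hi * 1000.0 >= 0
        ]
        if bands_nm:
            union = np.concatenate([np.linspace(y0, y1, 200) for y0, y1 in bands_nm])
            for (y0, y1), (lo, hi) in zip(bands_nm, bands_um):
                ys = np.linspace(y0, y1, 200)
                rec = {"band_um_below_neck": [lo, hi]}
                for side, name in ((_FLAT_SIGN, "flat"), (-_FLAT_SIGN, "round")):
                    tangent = self.shape.half_width(union, side).max()
                    rec[f"deviation_{name}_nm"] = float(
                        tangent - self.shape.half_width(ys, side).mean()
                    )
                self.flatness_truth.append(rec)
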