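"""Cell frame geometry: dynamic centre line, hemisphere partitions, flatness.

The conventions follow the acquisition geometry this package models: the
cell's apico-basal axis lies in-plane along ``y`` (base at low y), the
flattened/rounded lateral asymmetry is along ``x``, and serial sections
advance along ``z``.  All coordinates are physical nm.

The *dynamic centre line* is the per-section area centroid of the cell mask,
smoothed with a short moving average; it accounts for the asymmetric bulge
of the rounded side when dividing the cell into flattened and rounded
hemispheres.  The anterior/posterior split is made at the cell's mid-section
along ``z``, with the anterior hemisphere the one in which the cell first
appears; the modiolar/pillar naming of the x-axis split is anatomical and is
supplied by the caller (``flat_faces``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import LabelVolume

__all__ = [
    "CellFrame",
    "FlatnessProfile",
    "cell_mask_from_volume",
    "dynamic_centre_line",
    "partition_hemispheres",
    "flatness_profile",
    "infranuclear_mask",
    "build_cell_frame",
    "DEFAULT_FLATNESS_BANDS_UM",
]

#: depth bands below the neck used for the flatness metric, µm
DEFAULT_FLATNESS_BANDS_UM = ((1.0, 4.0), (5.0, 7.0), (7.0, 11.0))

_IN_CELL_CLASSES = ("cell", "nucleus", "membrane", "mitochondrion", "ribbon")

HEMISPHERE_AXES = ("flat_round", "mod_pillar", "ant_post")


def cell_mask_from_volume(volume: LabelVolume) -> np.ndarray:
    """Boolean mask of all voxels belonging to the cell body (any in-cell class)."""
    mask = np.zeros(volume.voxels.shape, dtype=bool)
    for cls in _IN_CELL_CLASSES:
        mask |= volume.mask(cls)
    return mask


def dynamic_centre_line(
    cell_mask: np.ndarray,
    voxel_size: tuple[float, float, float],
    smooth_sections: int = 5,
) -> np.ndarray:
    """Per-section centre of the cell: (nz, 2) array of (cx, cy) in nm.

    The centre is the area centroid of the section mask, smoothed with a
    ``smooth_sections``-section moving average.  Sections without cell are
    NaN; an empty section strictly inside the cell's z-range is an error.
    """
    sx, sy, _ = voxel_size
    nz = cell_mask.shape[0]
    line = np.full((nz, 2), np.nan)
    present = cell_mask.any(axis=(1, 2))
    zs = np.nonzero(present)[0]
    if len(zs) == 0:
        raise ValueError("cell mask is empty")
    missing = [int(z) for z in range(zs.min(), zs.max() + 1) if not present[z]]
    if missing:
        raise ValueError(f"cell mask empty on section(s) {missing} inside the cell z-range")
    for iz in zs:
        ys, xs = np.nonzero(cell_mask[iz])
        line[iz, 0] = xs.mean() * sx
        line[iz, 1] = ys.mean() * sy
    if smooth_sections > 1:
        k = smooth_sections
        vals = line[zs]
        kernel = np.ones(k) / k
        pad = k // 2
        for col in (0, 1):
            padded = np.pad(vals[:, col], pad, mode="edge")
            line[zs, col] = np.convolve(padded, kernel, mode="valid")[: len(zs)]
    return line


def partition_hemispheres(
    cell_mask: np.ndarray,
    centre_line: np.ndarray,
    axis_choice: str,
    voxel_size: tuple[float, float, float],
    flat_sign: int = -1,
    flat_faces: str = "pillar",
    anterior_low_z: bool = True,
) -> dict[str, np.ndarray]:
    """Partition the cell mask into two hemispheres along the chosen axis.

    ``flat_round`` and ``mod_pillar`` split along the y–z plane through the
    dynamic centre line (``flat_sign`` says which x side is the flattened
    one; ``flat_faces`` maps sides to modiolar/pillar).  ``ant_post`` splits
    at the cell's mid-section along z.  The two masks partition the cell mask
    exactly.
    """
    if axis_choice not in HEMISPHERE_AXES:
        raise ValueError(f"axis_choice must be one of {HEMISPHERE_AXES}, got {axis_choice!r}")
    sx = voxel_size[0]
    nz, ny, nx = cell_mask.shape
    if axis_choice == "ant_post":
        zs = np.nonzero(cell_mask.any(axis=(1, 2)))[0]
        z_mid = (zs.min() + zs.max()) // 2
        low = np.zeros_like(cell_mask)
        low[: z_mid + 1] = cell_mask[: z_mid + 1]
        high = cell_mask & ~low
        return (
            {"anterior": low, "posterior": high}
            if anterior_low_z
            else {"anterior": high, "posterior": low}
        )
    x_nm = np.arange(nx) * sx
    first = np.zeros_like(cell_mask)
    for iz in np.nonzero(cell_mask.any(axis=(1, 2)))[0]:
        cx = centre_line[iz, 0]
        if not np.isfinite(cx):
            continue
        side = (x_nm - cx) * flat_sign > 0
        first[iz] = cell_mask[iz] & side[None, :]
    second = cell_mask & ~first
    if axis_choice == "flat_round":
        return {"flat": first, "round": second}
    if flat_faces not in ("modiolar", "pillar"):
        raise ValueError("flat_faces must be 'modiolar' or 'pillar'")
    if flat_faces == "modiolar":
        return {"modiolar": first, "pillar": second}
    return {"pillar": first, "modiolar": second}


@dataclass
class FlatnessProfile:
    """Per-side mean deviation (nm) of the boundary from a tangent line.

    Deviations are measured on the cell's central section, per depth band
    below the neck; the tangent per side touches the maximal lateral extent
    over the union of bands.  Smaller deviation = flatter side.
    """

    bands_um: tuple[tuple[float, float], ...]
    deviation_nm: dict[str, list[float]]  # {"neg_x": [...], "pos_x": [...]}
    flat_sign: int  # -1 if the -x side is flatter
    tied: bool
    neck_y_nm: float


def _neck_y(cell_mask, nucleus_mask, voxel_size) -> float:
    """Neck = minimal cross-section area above the nucleus centre (nm along y)."""
    sy = voxel_size[1]
    area = cell_mask.sum(axis=(0, 2))  # per-y cross-section, voxels
    if nucleus_mask is not None and nucleus_mask.any():
        y_start = int(np.nonzero(nucleus_mask.any(axis=(0, 2)))[0].mean())
    else:
        ys = np.nonzero(area)[0]
        y_start = int(0.6 * ys.max())
    upper = area[y_start:]
    valid = np.nonzero(upper > 0)[0]
    if len(valid) == 0:
        raise ValueError("no cell sections above the nucleus: cannot locate the neck")
    rel = valid[np.argmin(upper[valid])]
    return float((y_start + rel) * sy)


def flatness_profile(
    cell_mask: np.ndarray,
    voxel_size: tuple[float, float, float],
    bands_um: tuple[tuple[float, float], ...] = DEFAULT_FLATNESS_BANDS_UM,
    nucleus_mask: np.ndarray | None = None,
    neck_y_nm: float | None = None,
    tie_break_sign: int = -1,
) -> FlatnessProfile:
    """Flatness metric: boundary deviation from perpendicular tangent lines.

    On the central section, a line parallel to the cell's long axis is placed
    tangent to each side's maximal lateral extent over the requested depth
    bands (measured in µm below the neck); the per-band mean distance from
    the boundary to that line is the side's deviation.  The flatter side is
    the one with the lower mean deviation across bands (ties flagged and
    broken toward ``tie_break_sign``).
    """
    sx, sy, _ = voxel_size
    zs = np.nonzero(cell_mask.any(axis=(1, 2)))[0]
    if len(zs) == 0:
        raise ValueError("cell mask is empty")
    iz_c = int(round(zs.mean()))
    sec = cell_mask[iz_c]
    if neck_y_nm is None:
        neck_y_nm = _neck_y(cell_mask, nucleus_mask, voxel_size)
    ys_cell = np.nonzero(sec.any(axis=1))[0]
    y_min_nm = ys_cell.min() * sy
    band_rows = []
    for lo, hi in bands_um:
        y1 = neck_y_nm - lo * 1000.0
        y0 = neck_y_nm - hi * 1000.0
        if y0 < y_min_nm - sy:
            raise ValueError(
                f"flatness band ({lo}, {hi}) µm below the neck exceeds the cell extent"
            )
        r0, r1 = int(np.ceil(y0 / sy)), int(np.floor(y1 / sy))
        rows = [r for r in range(r0, r1 + 1) if sec[r].any()]
        if not rows:
            raise ValueError(f"flatness band ({lo}, {hi}) µm contains no cell sections")
        band_rows.append(rows)
    union = sorted({r for rows in band_rows for r in rows})
    xmin = {r: np.nonzero(sec[r])[0].min() * sx for r in union}
    xmax = {r: np.nonzero(sec[r])[0].max() * sx for r in union}
    tan_neg = min(xmin[r] for r in union)
    tan_pos = max(xmax[r] for r in union)
    dev = {"neg_x": [], "pos_x": []}
    for rows in band_rows:
        dev["neg_x"].append(float(np.mean([xmin[r] - tan_neg for r in rows])))
        dev["pos_x"].append(float(np.mean([tan_pos - xmax[r] for r in rows])))
    m_neg = float(np.mean(dev["neg_x"]))
    m_pos = float(np.mean(dev["pos_x"]))
    tied = np.isclose(m_neg, m_pos, rtol=0, atol=0.25 * sx)
    if tied:
        flat_sign = tie_break_sign
    else:
        flat_sign = -1 if m_neg < m_pos else +1
    return FlatnessProfile(
        bands_um=tuple(tuple(b) for b in bands_um),
        deviation_nm=dev,
        flat_sign=flat_sign,
        tied=bool(tied),
        neck_y_nm=float(neck_y_nm),
    )


def infranuclear_mask(
    cell_mask: np.ndarray,
    nucleus_mask: np.ndarray,
    voxel_size: tuple[float, float, float],
    window_half_nm: float = 1500.0,
) -> tuple[np.ndarray, tuple[int, int]]:
    """Cell voxels basal to the nucleus, plus the peri-nuclear z-window.

    Returns ``(mask, (z0, z1))`` where the mask selects cell voxels strictly
    below the nucleus' basal-most extent along y, and ``(z0, z1)`` is the
    inclusive section range of the window ``window_half_nm`` either side of
    the nucleus' z midline (for partial-volume analyses).
    """
    if nucleus_mask is None or not nucleus_mask.any():
        raise ValueError("nucleus absent: infranuclear region is undefined")
    _, sy, sz = voxel_size
    y_basal = int(np.nonzero(nucleus_mask.any(axis=(0, 2)))[0].min())
    mask = np.zeros_like(cell_mask)
    mask[:, :y_basal, :] = cell_mask[:, :y_basal, :]
    z_mid = float(np.nonzero(nucleus_mask)[0].mean())
    half = window_half_nm / sz
    z0 = max(0, int(np.ceil(z_mid - half)))
    z1 = min(cell_mask.shape[0] - 1, int(np.floor(z_mid + half)))
    return mask, (z0, z1)


@dataclass
class CellFrame:
    """The cell's reference frame: axes, centre line, partitions, extents."""

    centre_line: np.ndarray  # (nz, 2) of (cx, cy) nm; NaN where no cell
    flat_sign: int
    flat_faces: str
    flatness: FlatnessProfile | None
    infranuclear: np.ndarray
    perinuclear_z: tuple[int, int]
    voxel_size: tuple[float, float, float]
    cell_mask: np.ndarray
    anterior_low_z: bool = True
    _hemi_cache: dict = field(default_factory=dict, repr=False)

    def hemispheres(self, axis_choice: str) -> dict[str, np.ndarray]:
        if axis_choice not in self._hemi_cache:
            self._hemi_cache[axis_choice] = partition_hemispheres(
                self.cell_mask,
                self.centre_line,
                axis_choice,
                self.voxel_size,
                flat_sign=self.flat_sign,
                flat_faces=self.flat_faces,
                anterior_low_z=self.anterior_low_z,
            )
        return self._hemi_cache[axis_choice]

    def side_of_points(self, xyz_nm: np.ndarray, axis_choice: str = "flat_round"):
        """Hemisphere name for each (x, y, z) nm point."""
        xyz = np.atleast_2d(np.asarray(xyz_nm, dtype=float))
        sz = self.voxel_size[2]
        names = self._axis_names(axis_choice)
        out = []
        if axis_choice == "ant_post":
            zs = np.nonzero(self.cell_mask.any(axis=(1, 2)))[0]
            z_mid = (zs.min() + zs.max()) // 2
            for x, y, z in xyz:
                low = int(round(z / sz)) <= z_mid
                out.append(names[0] if low == self.anterior_low_z else names[1])
            return out
        for x, y, z in xyz:
            iz = int(np.clip(round(z / sz), 0, len(self.centre_line) - 1))
            cx = self.centre_line[iz, 0]
            flatside = (x - cx) * self.flat_sign > 0
            out.append(names[0] if flatside else names[1])
        return out

    def _axis_names(self, axis_choice):
        if axis_choice == "flat_round":
            return ("flat", "round")
        if axis_choice == "ant_post":
            return ("anterior", "posterior")
        return (
            ("modiolar", "pillar") if self.flat_faces == "modiolar" else ("pillar", "modiolar")
        )


def build_cell_frame(
    volume: LabelVolume,
    flat_faces: str = "pillar",
    bands_um: tuple[tuple[float, float], ...] | None = None,
    smooth_sections: int = 5,
    anterior_low_z: bool = True,
) -> CellFrame:
    """Compute the full cell frame from a label volume.

    ``flat_faces`` states the anatomical orientation (whether the flattened
    side faces the modiolus or the pillar cell); it cannot be derived from a
    single-cell volume and must come from tissue context.
    """
    cell = cell_mask_from_volume(volume)
    nucleus = volume.mask("nucleus")
    line = dynamic_centre_line(cell, volume.voxel_size, smooth_sections)
    flat = None
    if bands_um is not None:
        flat = flatness_profile(
            cell, volume.voxel_size, bands_um=bands_um, nucleus_mask=nucleus
        )
        flat_sign = flat.flat_sign
    else:
        # fall back to bulk asymmetry: the flatter side has less lateral spread
        try:
            flat = flatness_profile(cell, volume.voxel_size, nucleus_mask=nucleus)
            flat_sign = flat.flat_sign
        except ValueError:
            ys, xs = np.nonzero(cell.any(axis=0))
            sx = volume.voxel_size[0]
            med = np.array([line[iz, 0] for iz in range(cell.shape[0])])
            cx = np.nanmean(med)
            spread_neg = cx - xs.min() * sx
            spread_pos = xs.max() * sx - cx
            flat_sign = -1 if spread_neg < spread_pos else +1
    infra, zwin = infranuclear_mask(cell, nucleus, volume.voxel_size)
    return CellFrame(
        centre_line=line,
        flat_sign=flat_sign,
        flat_faces=flat_faces,
        flatness=flat,
        infranuclear=infra,
        perinuclear_z=zwin,
        voxel_size=volume.voxel_size,
        cell_mask=cell,
        anterior_low_z=anterior_low_z,
    )
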