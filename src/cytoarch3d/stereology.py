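"""Point-counting stereology: grids, point classification, volume fractions.

A point grid is a systematic lattice of sample points in physical nm.  In
whole-cell mode grids are placed every 200 nm along the sectioning axis with
200 nm in-plane spacing; in partial mode grids sit on every 50 nm section
within a 3 µm window around the nucleus midline.  Each point takes the class
of its containing voxel (``not_in_cell`` / ``cytoplasm`` / ``membrane`` /
``mitochondrion``) and the volume fraction of a class set in a region is the
hit fraction among in-cell points, with the binomial standard error.

The grid origin is a systematic-uniform-random offset within one spacing
cell (seeded), which removes alignment bias with the voxel raster; a fixed
offset mode is provided for exact reproducibility of a given grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cell_geometry import CellFrame
from .io_formats import LabelVolume

__all__ = [
    "PointGrid",
    "FractionEstimate",
    "make_point_grid",
    "classify_points",
    "volume_fraction",
    "POINT_CLASSES",
]

POINT_CLASSES = ("not_in_cell", "cytoplasm", "membrane", "mitochondrion")

_CLASS_OF_SEMANTIC = {
    "membrane": "membrane",
    "mitochondrion": "mitochondrion",
    "cell": "cytoplasm",
    "nucleus": "cytoplasm",
    "ribbon": "cytoplasm",
    # terminals are outside the cell body; vesicles/tethers are below this
    # technique's resolution and are treated as cytoplasm if ever present
    "terminal": "not_in_cell",
    "vesicle": "cytoplasm",
    "tether": "cytoplasm",
    "background": "not_in_cell",
}


@dataclass
class PointGrid:
    """Systematic sample points (nm, xyz) with per-point classification."""

    points_nm: np.ndarray  # (n, 3)
    spacing_nm: tuple[float, float, float]
    mode: str
    origin_offset_nm: tuple[float, float, float]
    classes: np.ndarray | None = None  # per-point class string
    hemisphere_tags: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n_points(self) -> int:
        return len(self.points_nm)

    @property
    def n_classified(self) -> int:
        return 0 if self.classes is None else int(np.sum(self.classes != ""))


def make_point_grid(
    region_mask: np.ndarray,
    voxel_size: tuple[float, float, float],
    spacing_nm: tuple[float, float, float] = (200.0, 200.0, 200.0),
    mode: str = "whole",
    offset: str | tuple[float, float, float] = "sur",
    rng: np.random.Generator | int | None = None,
    z_window: tuple[int, int] | None = None,
) -> PointGrid:
    """Build a stereology point grid covering a region mask.

    ``mode='whole'``: points on a lattice with ``spacing_nm`` in all axes.
    ``mode='partial'``: grids on every section (z spacing = one section)
    within ``z_window`` (inclusive section indices), in-plane spacing from
    ``spacing_nm``.  ``offset='sur'`` draws a systematic-uniform-random
    origin within one spacing cell using ``rng``; a tuple gives a fixed
    offset.  Spacing below the voxel size is refused.
    """
    if mode not in ("whole", "partial"):
        raise ValueError(f"mode must be 'whole' or 'partial', got {mode!r}")
    if not region_mask.any():
        raise ValueError("region mask is empty")
    sx, sy, sz = voxel_size
    dx, dy, dz = (float(v) for v in spacing_nm)
    if dx < sx or dy < sy or (mode == "whole" and dz < sz):
        raise ValueError(
            f"grid spacing {spacing_nm} nm is below the voxel size {voxel_size} nm: "
            "sub-voxel sampling is meaningless"
        )
    if offset == "sur":
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        off = (rng.uniform(0, dx), rng.uniform(0, dy), rng.uniform(0, dz))
    else:
        off = tuple(float(v) for v in offset)  # type: ignore[arg-type]

    zs, ys, xs = np.nonzero(region_mask)
    x0, x1 = xs.min() * sx, xs.max() * sx
    y0, y1 = ys.min() * sy, ys.max() * sy
    gx = np.arange(x0 + off[0] % dx - dx, x1 + dx, dx)
    gx = gx[(gx >= x0 - sx / 2) & (gx <= x1 + sx / 2)]
    gy = np.arange(y0 + off[1] % dy - dy, y1 + dy, dy)
    gy = gy[(gy >= y0 - sy / 2) & (gy <= y1 + sy / 2)]
    if mode == "whole":
        z0, z1 = zs.min() * sz, zs.max() * sz
        gz = np.arange(z0 + off[2] % dz - dz, z1 + dz, dz)
        gz = gz[(gz >= z0 - sz / 2) & (gz <= z1 + sz / 2)]
    else:
        if z_window is None:
            z_window = (int(zs.min()), int(zs.max()))
        gz = np.arange(z_window[0], z_window[1] + 1) * sz
    xx, yy, zz = np.meshgrid(gx, gy, gz, indexing="ij")
    pts = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])
    return PointGrid(
        points_nm=pts,
        spacing_nm=(dx, dy, dz if mode == "whole" else sz),
        mode=mode,
        origin_offset_nm=tuple(off),
    )


def classify_points(
    grid: PointGrid, volume: LabelVolume, frame: CellFrame | None = None
) -> PointGrid:
    """Classify every grid point by its containing voxel's semantic class.

    Points outside the volume are an error (the grid must be built over a
    region of this volume).  With a :class:`CellFrame`, each point is also
    tagged with its hemisphere along every axis pair.
    """
    idx = volume.nm_to_index(grid.points_nm)
    nz, ny, nx = volume.voxels.shape
    oob = (
        (idx[:, 0] < 0)
        | (idx[:, 0] >= nz)
        | (idx[:, 1] < 0)
        | (idx[:, 1] >= ny)
        | (idx[:, 2] < 0)
        | (idx[:, 2] >= nx)
    )
    if oob.any():
        raise ValueError(f"{int(oob.sum())} grid points fall outside the volume extent")
    labels = volume.voxels[idx[:, 0], idx[:, 1], idx[:, 2]]
    class_of_label = {0: "not_in_cell"}
    class_of_label.update(
        {lab: _CLASS_OF_SEMANTIC[cls] for lab, cls in volume.label_table.items()}
    )
    lut_keys = np.array(sorted(class_of_label))
    lut_vals = np.array([class_of_label[k] for k in lut_keys])
    classes = lut_vals[np.searchsorted(lut_keys, labels)]
    tags: dict[str, np.ndarray] = {}
    if frame is not None:
        for axis in ("flat_round", "ant_post", "mod_pillar"):
            tags[axis] = np.array(frame.side_of_points(grid.points_nm, axis))
    return PointGrid(
        points_nm=grid.points_nm,
        spacing_nm=grid.spacing_nm,
        mode=grid.mode,
        origin_offset_nm=grid.origin_offset_nm,
        classes=classes,
        hemisphere_tags=tags,
    )


@dataclass
class FractionEstimate:
    """A point-counting volume-fraction estimate for one region."""

    region: str
    n_points: int  # in-cell points in the region
    n_hits: int
    fraction: float
    se: float
    hits_by_class: dict[str, int] = field(default_factory=dict)


def volume_fraction(
    grid: PointGrid,
    class_set: tuple[str, ...] = ("membrane", "mitochondrion"),
    region: np.ndarray | str | None = None,
    region_name: str | None = None,
    hemisphere_axis: str = "flat_round",
) -> FractionEstimate:
    """Volume fraction of ``class_set`` among in-cell points in a region.

    ``region`` may be a boolean selector over grid points, a hemisphere name
    (resolved through the grid's hemisphere tags), or None for all points.
    The standard error is binomial, √(p(1−p)/n).
    """
    if grid.classes is None:
        raise ValueError("grid is unclassified: run classify_points first")
    unknown = set(class_set) - set(POINT_CLASSES)
    if unknown:
        raise ValueError(f"unknown point classes {sorted(unknown)}")
    if region is None:
        sel = np.ones(grid.n_points, dtype=bool)
        name = region_name or "all"
    elif isinstance(region, str):
        found = None
        for axis, tags in grid.hemisphere_tags.items():
            if region in tags:
                found = tags == region
                break
        if found is None:
            tags = grid.hemisphere_tags.get(hemisphere_axis)
            if tags is None:
                raise ValueError(f"no hemisphere tags for region {region!r}")
            found = tags == region
        sel = found
        name = region_name or region
    else:
        sel = np.asarray(region, dtype=bool)
        name = region_name or "region"
    in_cell = sel & (grid.classes != "not_in_cell")
    n = int(in_cell.sum())
    if n == 0:
        raise ValueError(f"region {name!r} contains no in-cell points")
    hit = in_cell & np.isin(grid.classes, class_set)
    k = int(hit.sum())
    p = k / n
    se = float(np.sqrt(p * (1 - p) / n))
    by_class = {
        cls: int(np.sum(in_cell & (grid.classes == cls))) for cls in POINT_CLASSES[1:]
    }
    return FractionEstimate(
        region=name, n_points=n, n_hits=k, fraction=float(p), se=se, hits_by_class=by_class
    )
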