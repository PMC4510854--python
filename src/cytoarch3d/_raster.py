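"""Anisotropic nm-space rasterization helpers.

All geometry is defined in physical nm (x, y, z) and rasterized onto
``(z, y, x)`` index grids with voxel size ``(sx, sy, sz)`` nm, voxel-centre
convention: voxel ``(iz, iy, ix)`` is centred at ``(ix*sx, iy*sy, iz*sz)``.
"""

from __future__ import annotations

import numpy as np

__all__ = ["ellipsoid_indices", "sphere_indices", "segment_indices", "polyline_length_nm"]


def ellipsoid_indices(
    shape: tuple[int, int, int],
    voxel_size: tuple[float, float, float],
    center_nm: tuple[float, float, float],
    semiaxes_nm: tuple[float, float, float],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Voxel indices (iz, iy, ix) inside an axis-aligned ellipsoid.

    ``center_nm`` and ``semiaxes_nm`` are (x, y, z) in nm.  Returns index
    arrays clipped to the volume bounds.
    """
    nz, ny, nx = shape
    sx, sy, sz = voxel_size
    cx, cy, cz = center_nm
    rx, ry, rz = semiaxes_nm
    ix0 = max(0, int(np.floor((cx - rx) / sx)))
    ix1 = min(nx - 1, int(np.ceil((cx + rx) / sx)))
    iy0 = max(0, int(np.floor((cy - ry) / sy)))
    iy1 = min(ny - 1, int(np.ceil((cy + ry) / sy)))
    iz0 = max(0, int(np.floor((cz - rz) / sz)))
    iz1 = min(nz - 1, int(np.ceil((cz + rz) / sz)))
    if ix1 < ix0 or iy1 < iy0 or iz1 < iz0:
        empty = np.empty(0, dtype=np.int64)
        return empty, empty.copy(), empty.copy()
    zz, yy, xx = np.meshgrid(
        np.arange(iz0, iz1 + 1), np.arange(iy0, iy1 + 1), np.arange(ix0, ix1 + 1), indexing="ij"
    )
    inside = (
        ((xx * sx - cx) / rx) ** 2 + ((yy * sy - cy) / ry) ** 2 + ((zz * sz - cz) / rz) ** 2
    ) <= 1.0
    return zz[inside].ravel(), yy[inside].ravel(), xx[inside].ravel()


def sphere_indices(shape, voxel_size, center_nm, radius_nm):
    """Voxel indices inside a sphere of physical radius ``radius_nm``."""
    return ellipsoid_indices(shape, voxel_size, center_nm, (radius_nm,) * 3)


def segment_indices(
    shape: tuple[int, int, int],
    voxel_size: tuple[float, float, float],
    p0_nm: np.ndarray,
    p1_nm: np.ndarray,
    radius_nm: float = 0.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Voxel indices of a rasterized straight segment from p0 to p1 (nm, xyz).

    ``radius_nm > 0`` thickens the line to a tube of that physical radius
    (approximated by stamping spheres along the segment).
    """
    p0 = np.asarray(p0_nm, dtype=float)
    p1 = np.asarray(p1_nm, dtype=float)
    sx, sy, sz = voxel_size
    step = 0.4 * min(voxel_size)
    n = max(2, int(np.ceil(np.linalg.norm(p1 - p0) / step)) + 1)
    t = np.linspace(0.0, 1.0, n)
    pts = p0[None, :] + t[:, None] * (p1 - p0)[None, :]
    if radius_nm <= 0:
        iz = np.rint(pts[:, 2] / sz).astype(np.int64)
        iy = np.rint(pts[:, 1] / sy).astype(np.int64)
        ix = np.rint(pts[:, 0] / sx).astype(np.int64)
        nz, ny, nx = shape
        ok = (iz >= 0) & (iz < nz) & (iy >= 0) & (iy < ny) & (ix >= 0) & (ix < nx)
        flat = np.unique(iz[ok] * (ny * nx) + iy[ok] * nx + ix[ok])
        return flat // (ny * nx), (flat // nx) % ny, flat % nx
    parts = [sphere_indices(shape, voxel_size, tuple(p), radius_nm) for p in pts[:: max(1, n // 64)]]
    # stamping at ~64 stations is enough for radii >= one voxel
    nz, ny, nx = shape
    flat = np.unique(
        np.concatenate([z * (ny * nx) + y * nx + x for z, y, x in parts])
        if parts
        else np.empty(0, dtype=np.int64)
    )
    return flat // (ny * nx), (flat // nx) % ny, flat % nx


def polyline_length_nm(points_nm: np.ndarray) -> float:
    """Arc length of an (n, k) polyline in nm."""
    pts = np.asarray(points_nm, dtype=float)
    if len(pts) < 2:
        return 0.0
    return float(np.sqrt(((pts[1:] - pts[:-1]) ** 2).sum(axis=1)).sum())
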