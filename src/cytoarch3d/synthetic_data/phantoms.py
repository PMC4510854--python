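"""Small analytic phantoms with planted summary statistics."""

from __future__ import annotations

import numpy as np

__all__ = ["generate_region_share_phantom"]


def generate_region_share_phantom(
    volume_share: float = 0.369,
    area_share: float = 0.688,
    shape: tuple[int, int, int] = (10, 100, 40),
    total_area_um2: float = 100.0,
):
    """Box phantom with planted region volume- and sheet-area shares.

    Returns ``(region_mask, cytoplasm_mask, sheet_masks, sheet_areas_um2)``
    where the region is a y-slab holding exactly ``volume_share`` of the
    cytoplasm and one of two planar sheets lies inside it carrying
    ``area_share`` of the total sheet area.
    """
    if not 0 < volume_share < 1 or not 0 < area_share < 1:
        raise ValueError("shares must lie strictly between 0 and 1")
    nz, ny, nx = shape
    cyto = np.ones(shape, dtype=bool)
    cut = int(round(volume_share * ny))
    region = np.zeros(shape, dtype=bool)
    region[:, :cut, :] = True
    inner = np.zeros(shape, dtype=bool)
    inner[nz // 3, cut // 2, 4 : nx - 4] = True
    outer = np.zeros(shape, dtype=bool)
    outer[2 * nz // 3, (cut + ny) // 2, 4 : nx - 4] = True
    areas = [area_share * total_area_um2, (1.0 - area_share) * total_area_um2]
    actual_share = region[:, :cut, :].sum() / cyto.sum()
    assert abs(actual_share - volume_share) < 0.01
    return region, cyto, [inner, outer], areas
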