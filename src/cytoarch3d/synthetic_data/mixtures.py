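"""Numeric sampling of the three-component sheet-area mixture.

The membrane census of a reconstructed cell shows three very large sheets, a
handful of intermediate sheets and thousands of small ones; areas within each
class are modelled as gamma-distributed with the class mean/sd.  Sampling the
mixture directly (without rasterizing a volume) gives planted-partition
instances for the sheet classifier.
"""

from __future__ import annotations

import numpy as np

from .params import SheetAreaMixture, gamma_from_mean_sd

__all__ = ["sample_sheet_areas"]


def sample_sheet_areas(
    mixture: SheetAreaMixture | None = None,
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw per-sheet areas (µm²) and true type labels (1, 2, 3).

    Returns ``(areas, labels)`` in a fixed order (Type 1 first); areas are
    strictly positive.
    """
    if mixture is None:
        mixture = SheetAreaMixture.reference_scale()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    means = mixture.mean_areas_um2 or SheetAreaMixture.reference_scale().mean_areas_um2
    sds = mixture.sd_areas_um2 or SheetAreaMixture.reference_scale().sd_areas_um2
    areas, labels = [], []
    for t, (n, m, s) in enumerate(zip(mixture.counts, means, sds), start=1):
        draw = gamma_from_mean_sd(rng, m, s, n)
        draw = np.maximum(draw, 1e-3)  # areas are physical; keep strictly positive
        areas.append(draw)
        labels.append(np.full(n, t, dtype=int))
    return np.concatenate(areas), np.concatenate(labels)
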