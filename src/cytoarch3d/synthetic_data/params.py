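"""Generator parameter sets.

The defaults describe the imaging and biology this package emulates: a
flask-shaped inner hair cell ~15 µm wide and ~30 µm tall imaged at
19×19×50 nm voxels, with ~11 µm of infranuclear cytoplasm; an intracellular
membrane network plus mitochondria occupying ~23% of the flattened and ~16%
of the rounded hemisphere; ~16 afferent terminals biased to the flattened
side; and tomogram-scale (2 nm isotropic) fields of ~37 nm vesicles tethered
by 20–55 nm links in five structural contexts.

Full-scale cells are expensive; the ``small()`` / ``medium()`` presets give
the same construction at reduced dimensions and object counts for desk-scale
analysis and are what the test-suite problem sizes use.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Mapping

import numpy as np

__all__ = [
    "SheetAreaMixture",
    "CellGenParams",
    "TomoGenParams",
    "LINK_CONTEXTS",
    "GeometryInfeasibleError",
]


class GeometryInfeasibleError(ValueError):
    """Requested phantom geometry cannot be packed; message names the constraint."""


@dataclass(frozen=True)
class SheetAreaMixture:
    """Three-component membrane-sheet area mixture (Type 1 / Type 2 / Type 3).

    ``counts`` are per-type sheet counts; ``mean_areas_um2`` / ``sd_areas_um2``
    parameterize per-type gamma area distributions (µm², face-area convention).
    ``reference_scale()`` reproduces the reference per-cell summary: 3 very large
    sheets, 8 intermediate sheets and 2073 small sheets with mean areas of
    roughly 38,000 / 2383 / 85 µm² (sd back-computed from s.e.m.·√n).
    """

    counts: tuple[int, int, int] = (3, 8, 200)
    mean_areas_um2: tuple[float, float, float] | None = None
    sd_areas_um2: tuple[float, float, float] | None = None

    def __post_init__(self):
        if len(self.counts) != 3 or any(c < 0 for c in self.counts):
            raise ValueError(f"mixture counts must be 3 non-negative ints, got {self.counts}")
        for name in ("mean_areas_um2", "sd_areas_um2"):
            v = getattr(self, name)
            if v is not None and (len(v) != 3 or any(x <= 0 for x in v)):
                raise ValueError(f"{name} must be 3 positive values, got {v}")

    @staticmethod
    def reference_scale() -> "SheetAreaMixture":
        return SheetAreaMixture(
            counts=(3, 8, 2073),
            mean_areas_um2=(38000.0, 2383.0, 85.0),
            sd_areas_um2=(15000.0, 863.0, 91.0),
        )

    @staticmethod
    def separated(n_type3: int = 2000) -> "SheetAreaMixture":
        """A well log-area-separated 3/8/n₃ census (planted-partition setting)."""
        return SheetAreaMixture(
            counts=(3, 8, int(n_type3)),
            mean_areas_um2=(40000.0, 2400.0, 85.0),
            sd_areas_um2=(8000.0, 400.0, 60.0),
        )


@dataclass(frozen=True)
class CellGenParams:
    """Parameters for the cell-scale phantom generator.

    All dimensions in µm unless suffixed ``_nm``; probabilities in [0, 1].
    """

    voxel_size: tuple[float, float, float] = (19.0, 19.0, 50.0)  # (x, y, z) nm
    cell_height_um: float = 30.0  # apico-basal length (y axis)
    cell_width_um: float = 15.0  # radial width (x axis, flat+round)
    cell_depth_um: float | None = None  # sectioning-axis width (z); default = width
    infranuclear_fraction: float = 11.0 / 30.0  # cell length below the nucleus
    flatness_contrast: float = 3.0  # rounded/flattened lateral bulge ratio
    n_terminals: int = 16
    p_flat_terminal: float = 0.63  # 10.1 of 16.1 terminals on the flattened side
    terminal_radius_nm: float = 400.0
    n_ribbons: int = 16
    ribbon_radius_nm: float = 150.0
    membrane_fraction_flat: float | None = 0.23
    membrane_fraction_round: float | None = 0.16
    membrane_fraction_anterior: float | None = None
    membrane_fraction_posterior: float | None = None
    sheet_area_mixture: SheetAreaMixture = field(default_factory=SheetAreaMixture)
    p_mito_association: float = 0.96
    mito_semiaxes_nm: tuple[float, float, float] = (250.0, 350.0, 250.0)  # (x, y, z)
    ribbon_type3_distance_nm: float = 515.0
    ribbon_type3_distance_sd_nm: float = 370.0
    seed: int = 0

    def __post_init__(self):
        for name in ("p_flat_terminal", "p_mito_association"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in (
            "membrane_fraction_flat",
            "membrane_fraction_round",
            "membrane_fraction_anterior",
            "membrane_fraction_posterior",
        ):
            v = getattr(self, name)
            if v is not None and not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if any(s <= 0 for s in self.voxel_size):
            raise ValueError(f"voxel_size must be positive, got {self.voxel_size}")
        if self.cell_height_um <= 0 or self.cell_width_um <= 0:
            raise ValueError("cell dimensions must be positive")
        if self.flatness_contrast < 1.0:
            raise ValueError(
                "flatness_contrast is the rounded/flattened bulge ratio and must be >= 1"
            )
        flat_axis = self.membrane_fraction_flat is not None or self.membrane_fraction_round is not None
        ap_axis = (
            self.membrane_fraction_anterior is not None
            or self.membrane_fraction_posterior is not None
        )
        if flat_axis and ap_axis:
            raise ValueError(
                "membrane fractions can be planted along one hemisphere axis per cell "
                "(flat/round or anterior/posterior, not both)"
            )
        if self.n_terminals < 0 or self.n_ribbons < 0:
            raise ValueError("object counts must be non-negative")

    # -- presets -----------------------------------------------------------------

    @property
    def depth_um(self) -> float:
        return self.cell_depth_um if self.cell_depth_um is not None else self.cell_width_um

    @staticmethod
    def small(seed: int = 0, **overrides) -> "CellGenParams":
        """A ~4×8×4 µm cell with reduced object counts; same construction."""
        base = dict(
            cell_height_um=8.0,
            cell_width_um=4.0,
            cell_depth_um=4.0,
            n_terminals=16,
            terminal_radius_nm=350.0,
            n_ribbons=6,
            sheet_area_mixture=SheetAreaMixture(counts=(2, 3, 24)),
            seed=seed,
        )
        base.update(overrides)
        return CellGenParams(**base)

    @staticmethod
    def medium(seed: int = 0, **overrides) -> "CellGenParams":
        """A ~6×12×6 µm cell able to host the full 3+8+200 sheet census."""
        base = dict(
            cell_height_um=12.0,
            cell_width_um=6.0,
            cell_depth_um=6.0,
            n_terminals=16,
            n_ribbons=8,
            sheet_area_mixture=SheetAreaMixture(counts=(3, 8, 200)),
            seed=seed,
        )
        base.update(overrides)
        return CellGenParams(**base)

    @staticmethod
    def shape_only(seed: int = 0, **overrides) -> "CellGenParams":
        """Cell mask + nucleus only — fast path for geometry tests."""
        base = dict(
            cell_height_um=6.0,
            cell_width_um=3.0,
            cell_depth_um=3.0,
            n_terminals=0,
            n_ribbons=0,
            sheet_area_mixture=SheetAreaMixture(counts=(0, 0, 0)),
            membrane_fraction_flat=None,
            membrane_fraction_round=None,
            seed=seed,
        )
        base.update(overrides)
        return CellGenParams(**base)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sheet_area_mixture"] = asdict(self.sheet_area_mixture)
        return d

    def with_(self, **overrides) -> "CellGenParams":
        return replace(self, **overrides)


#: the five tether context classes
LINK_CONTEXTS = (
    "mito-RER",
    "vesicle-RER",
    "vesicle-vesicle@RER",
    "vesicle-vesicle@ribbon",
    "vesicle-ribbon",
)

_DEFAULT_LINK_MEANS = {
    "mito-RER": 30.9,
    "vesicle-RER": 52.9,
    "vesicle-vesicle@RER": 45.4,
    "vesicle-vesicle@ribbon": 22.3,
    "vesicle-ribbon": 26.8,
}
# per-link sd back-computed from the reference s.e.m. and n
_DEFAULT_LINK_SDS = {
    "mito-RER": 8.6,
    "vesicle-RER": 26.2,
    "vesicle-vesicle@RER": 23.4,
    "vesicle-vesicle@ribbon": 6.2,
    "vesicle-ribbon": 10.8,
}
_DEFAULT_LINK_COUNTS = {
    "mito-RER": 44,
    "vesicle-RER": 63,
    "vesicle-vesicle@RER": 61,
    "vesicle-vesicle@ribbon": 78,
    "vesicle-ribbon": 36,
}


@dataclass(frozen=True)
class TomoGenParams:
    """Parameters for the tomogram-scale phantom generator (nm units)."""

    voxel_size_nm: float = 2.0  # isotropic
    vesicle_diameter_mean: float = 37.3
    vesicle_diameter_sd: float = 5.0
    ribbon_vesicle_diameter_mean: float = 36.3  # vesicles at the ribbon run slightly smaller
    ribbon_vesicle_diameter_sd: float = 4.7
    link_length_means: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_LINK_MEANS)
    )
    link_length_sds: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_LINK_SDS))
    counts: Mapping[str, int] = field(default_factory=lambda: dict(_DEFAULT_LINK_COUNTS))
    n_free_vesicles: int = 6
    ribbon_radius_nm: float = 220.0
    seed: int = 0

    def __post_init__(self):
        if self.voxel_size_nm <= 0:
            raise ValueError("voxel_size_nm must be positive")
        for d in (self.vesicle_diameter_mean, self.ribbon_vesicle_diameter_mean):
            if d <= 0:
                raise ValueError("vesicle diameters must be positive")
        unknown = set(self.counts) - set(LINK_CONTEXTS)
        if unknown:
            raise ValueError(
                f"unknown link contexts {sorted(unknown)}; allowed: {LINK_CONTEXTS}"
            )
        for ctx, m in self.link_length_means.items():
            if ctx not in LINK_CONTEXTS:
                raise ValueError(f"unknown link context {ctx!r}; allowed: {LINK_CONTEXTS}")
            if m <= 0:
                raise ValueError(f"link length mean for {ctx!r} must be positive")
        for ctx, n in self.counts.items():
            if n < 0:
                raise ValueError(f"count for {ctx!r} must be non-negative")

    @staticmethod
    def scaled(factor: float, seed: int = 0, **overrides) -> "TomoGenParams":
        """Same geometry with per-context counts scaled by ``factor``."""
        counts = {k: max(0, int(round(v * factor))) for k, v in _DEFAULT_LINK_COUNTS.items()}
        base = dict(counts=counts, n_free_vesicles=max(2, int(6 * factor)), seed=seed)
        base.update(overrides)
        return TomoGenParams(**base)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["link_length_means"] = dict(self.link_length_means)
        d["link_length_sds"] = dict(self.link_length_sds)
        d["counts"] = dict(self.counts)
        return d


def gamma_from_mean_sd(rng: np.random.Generator, mean: float, sd: float, size: int) -> np.ndarray:
    """Positive random sample with the requested mean and sd (gamma family)."""
    if size == 0:
        return np.empty(0)
    if sd <= 0:
        return np.full(size, mean)
    shape = (mean / sd) ** 2
    scale = sd**2 / mean
    return rng.gamma(shape, scale, size=size)
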