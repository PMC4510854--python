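"""Spatial statistics linking mitochondria, sheets, ribbons and terminals,
plus the group-level tests used for between-condition comparisons.

Distance conventions: all distances are Euclidean in nm after scaling voxel
indices by the voxel size (anisotropy-aware).  Organelle-to-organelle
distances use voxel positions on both sides; only ribbons are reduced to
their approximate centre.  The surface *gap* between two voxelized objects
is the minimal voxel-centre distance minus one in-plane voxel pitch
(floored at zero), so face-contact in-plane reads as a zero gap; "close
association" means gap ≤ ``gap_threshold_nm`` (default one in-plane voxel —
the operational form of "no visible gap" in section images).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from scipy.spatial import cKDTree

from .cell_geometry import CellFrame
from .io_formats import LabelVolume
from .sheet_assembly import Sheet

__all__ = [
    "AssociationRecord",
    "DistanceRecord",
    "TerminalRecord",
    "mito_membrane_association",
    "mito_density_per_type",
    "ribbon_to_sheet_distances",
    "terminal_distribution",
    "region_membrane_share",
    "games_howell",
    "run_group_tests",
]


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _instances(volume: LabelVolume, semantic_class: str) -> dict[int, np.ndarray]:
    """Per-instance voxel index arrays (n, 3) of (iz, iy, ix) for a class.

    Instances are the distinct labels of the class; a single label is split
    by 3D connected components.
    """
    labs = volume.labels_of(semantic_class)
    out: dict[int, np.ndarray] = {}
    if not labs:
        return out
    if len(labs) == 1:
        mask = volume.voxels == labs[0]
        cc, n = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=bool))
        for i in range(1, n + 1):
            out[i] = np.argwhere(cc == i)
        return out
    sel = np.isin(volume.voxels, labs)
    coords = np.argwhere(sel)
    vals = volume.voxels[sel]
    order = np.argsort(vals, kind="stable")
    coords, vals = coords[order], vals[order]
    cuts = np.searchsorted(vals, labs)
    for i, lab in enumerate(labs):
        j0 = cuts[i]
        j1 = cuts[i + 1] if i + 1 < len(labs) else len(vals)
        if j1 > j0:
            out[int(lab)] = coords[j0:j1]
    return out


def _to_nm(coords_zyx: np.ndarray, voxel_size) -> np.ndarray:
    sx, sy, sz = voxel_size
    return np.column_stack(
        [coords_zyx[:, 2] * sx, coords_zyx[:, 1] * sy, coords_zyx[:, 0] * sz]
    )


def _sheet_trees_by_type(
    sheets: Sequence[Sheet], voxel_size
) -> dict[int, cKDTree]:
    coords: dict[int, list] = {}
    for sh in sheets:
        t = sh.class_label
        if t is None:
            raise ValueError("sheets must be classified (class_label set)")
        zz, yy, xx = sh.voxel_indices()
        coords.setdefault(int(t), []).append(
            _to_nm(np.column_stack([zz, yy, xx]), voxel_size)
        )
    return {t: cKDTree(np.concatenate(c)) for t, c in coords.items()}


# ---------------------------------------------------------------------------
# mitochondrion ↔ membrane association
# ---------------------------------------------------------------------------


@dataclass
class AssociationRecord:
    mito_id: int
    distance_nm: float  # minimal voxel-centre distance to any membrane
    gap_nm: float
    associated: bool
    gap_by_type_nm: dict[int, float] = field(default_factory=dict)
    types_touched: tuple[int, ...] = ()

    @property
    def n_types_touched(self) -> int:
        return len(self.types_touched)


def mito_membrane_association(
    volume: LabelVolume,
    sheets: Sequence[Sheet],
    gap_threshold_nm: float | None = None,
) -> tuple[list[AssociationRecord], dict]:
    """Per-mitochondrion membrane association and the population summary.

    The gap threshold defaults to one in-plane voxel.  Returns the records
    plus a summary with the associated fraction and the fraction of
    associated mitochondria touching exactly one membrane type.
    """
    sx = volume.voxel_size[0]
    if gap_threshold_nm is None:
        gap_threshold_nm = sx
    mitos = _instances(volume, "mitochondrion")
    if not mitos:
        raise ValueError("no mitochondria in volume")
    trees = _sheet_trees_by_type(sheets, volume.voxel_size)
    records = []
    for mid in sorted(mitos):
        xyz = _to_nm(mitos[mid], volume.voxel_size)
        by_type = {}
        for t, tree in trees.items():
            d, _ = tree.query(xyz)
            by_type[t] = float(max(0.0, d.min() - sx))
        dist = min((g + sx for g in by_type.values()), default=float("inf"))
        gap = min(by_type.values(), default=float("inf"))
        touched = tuple(sorted(t for t, g in by_type.items() if g <= gap_threshold_nm))
        records.append(
            AssociationRecord(
                mito_id=int(mid),
                distance_nm=float(dist),
                gap_nm=float(gap),
                associated=gap <= gap_threshold_nm,
                gap_by_type_nm=by_type,
                types_touched=touched,
            )
        )
    n = len(records)
    n_assoc = sum(r.associated for r in records)
    single = sum(1 for r in records if r.n_types_touched == 1)
    summary = {
        "n_mitochondria": n,
        "n_associated": n_assoc,
        "associated_fraction": n_assoc / n,
        "associated_se": float(np.sqrt(n_assoc / n * (1 - n_assoc / n) / n)),
        "single_type_fraction": single / n,
        "gap_threshold_nm": float(gap_threshold_nm),
    }
    return records, summary


def mito_density_per_type(
    records: Sequence[AssociationRecord], type_areas_um2: Mapping[int, float]
) -> pd.DataFrame:
    """Mitochondrial density per membrane type, µm⁻².

    Only mitochondria associated with a single membrane type are counted;
    density = count / total area of that type.
    """
    rows = []
    for t in sorted(type_areas_um2):
        area = float(type_areas_um2[t])
        if area <= 0:
            raise ValueError(f"type {t} has zero area: density undefined")
        count = sum(
            1 for r in records if r.associated and r.types_touched == (t,)
        )
        rows.append(
            {"type": t, "n_single_type_mitochondria": count, "area_um2": area,
             "density_per_um2": count / area}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ribbon ↔ sheet distances
# ---------------------------------------------------------------------------


@dataclass
class DistanceRecord:
    ribbon_id: int
    centre_nm: tuple[float, float, float]
    distance_by_type_nm: dict[int, float]
    nearest_type: int | None


def ribbon_to_sheet_distances(
    volume: LabelVolume, sheets: Sequence[Sheet]
) -> tuple[list[DistanceRecord], pd.DataFrame]:
    """Distance from each ribbon's centre to the nearest sheet point, per type.

    The ribbon is reduced to its approximate centre (voxel centroid); the
    sheet side uses every member voxel.  Types absent from the census are
    reported as missing, never as infinity.  Returns per-ribbon records and
    a per-type mean±SE table.
    """
    ribbons = _instances(volume, "ribbon")
    if not ribbons:
        raise ValueError("no ribbons in volume")
    trees = _sheet_trees_by_type(sheets, volume.voxel_size)
    records = []
    for rid in sorted(ribbons):
        centre = _to_nm(ribbons[rid], volume.voxel_size).mean(axis=0)
        dists = {}
        for t, tree in trees.items():
            d, _ = tree.query(centre)
            dists[int(t)] = float(d)
        nearest = min(dists, key=dists.get) if dists else None
        records.append(
            DistanceRecord(
                ribbon_id=int(rid),
                centre_nm=tuple(float(v) for v in centre),
                distance_by_type_nm=dists,
                nearest_type=nearest,
            )
        )
    rows = []
    for t in sorted(trees):
        vals = np.array([r.distance_by_type_nm[t] for r in records])
        rows.append(
            {
                "type": t,
                "n_ribbons": len(vals),
                "mean_nm": float(vals.mean()),
                "se_nm": float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else float("nan"),
                "n_nearest": sum(1 for r in records if r.nearest_type == t),
            }
        )
    return records, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# terminals
# ---------------------------------------------------------------------------


@dataclass
class TerminalRecord:
    terminal_id: int
    centre_nm: tuple[float, float, float]
    hemisphere_flat_round: str
    hemisphere_mod_pillar: str
    longitudinal_nm: float  # distance from the basal pole along the long axis
    representation: str = "segmented"


def terminal_distribution(
    volume: LabelVolume, frame: CellFrame
) -> tuple[list[TerminalRecord], dict]:
    """Hemisphere counts of afferent terminals and the apical-most terminal.

    Terminals are located by their voxel centroid; the longitudinal position
    is the straight-axis distance from the basal pole.  The summary reports
    counts per hemisphere pair and the modiolar/pillar side of the terminal
    furthest from the synaptic (basal) pole.
    """
    terminals = _instances(volume, "terminal")
    if not terminals:
        raise ValueError("no terminals in volume")
    sy = volume.voxel_size[1]
    y_base = np.nonzero(frame.cell_mask.any(axis=(0, 2)))[0].min() * sy
    records = []
    for tid in sorted(terminals):
        centre = _to_nm(terminals[tid], volume.voxel_size).mean(axis=0)
        fr = frame.side_of_points(centre, "flat_round")[0]
        mp = frame.side_of_points(centre, "mod_pillar")[0]
        records.append(
            TerminalRecord(
                terminal_id=int(tid),
                centre_nm=tuple(float(v) for v in centre),
                hemisphere_flat_round=fr,
                hemisphere_mod_pillar=mp,
                longitudinal_nm=float(centre[1] - y_base),
            )
        )
    counts = {
        "flat": sum(r.hemisphere_flat_round == "flat" for r in records),
        "round": sum(r.hemisphere_flat_round == "round" for r in records),
        "modiolar": sum(r.hemisphere_mod_pillar == "modiolar" for r in records),
        "pillar": sum(r.hemisphere_mod_pillar == "pillar" for r in records),
    }
    extremum = max(records, key=lambda r: r.longitudinal_nm)
    summary = {
        "counts": counts,
        "n_terminals": len(records),
        "flat_majority": counts["flat"] > counts["round"],
        "extremum_terminal_id": extremum.terminal_id,
        "extremum_side_mod_pillar": extremum.hemisphere_mod_pillar,
        "extremum_longitudinal_nm": extremum.longitudinal_nm,
    }
    return records, summary


# ---------------------------------------------------------------------------
# region shares
# ---------------------------------------------------------------------------


def region_membrane_share(
    region_mask: np.ndarray,
    sheets: Sequence[Sheet],
    cytoplasm_mask: np.ndarray,
    areas_um2: Sequence[float] | None = None,
) -> tuple[float, float]:
    """A region's share of cytoplasmic volume and of total sheet area.

    The area share apportions each sheet's area by the fraction of its
    voxels inside the region.  An empty region is an error, not (0, 0).
    """
    if not region_mask.any():
        raise ValueError("region mask is empty")
    if not cytoplasm_mask.any():
        raise ValueError("cytoplasm mask is empty")
    extra = region_mask & ~cytoplasm_mask
    if extra.any():
        raise ValueError("region must be a subset of the cytoplasm mask")
    vol_share = float(region_mask.sum() / cytoplasm_mask.sum())
    if areas_um2 is None:
        areas_um2 = [sh.area_um2 for sh in sheets]
        if any(a is None for a in areas_um2):
            raise ValueError("sheets must carry areas (run sheet_area first)")
    total = float(np.sum(areas_um2))
    inside = 0.0
    for sh, area in zip(sheets, areas_um2):
        zz, yy, xx = sh.voxel_indices()
        frac_in = float(region_mask[zz, yy, xx].mean())
        inside += area * frac_in
    return vol_share, inside / total if total else float("nan")


# ---------------------------------------------------------------------------
# group tests
# ---------------------------------------------------------------------------


def games_howell(samples: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """Games–Howell post hoc pairwise comparisons (unequal variances/sizes).

    For each pair, the Welch statistic t = (m_i − m_j)/√(s_i²/n_i + s_j²/n_j)
    with Welch–Satterthwaite degrees of freedom is referred to the
    studentized-range distribution with k groups: p = P(Q ≥ |t|·√2).
    """
    names = sorted(samples)
    k = len(names)
    if k < 2:
        raise ValueError("need at least two groups")
    desc = {
        g: (np.mean(samples[g]), np.var(samples[g], ddof=1), len(samples[g]))
        for g in names
    }
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = names[i], names[j]
            ma, va, na = desc[a]
            mb, vb, nb = desc[b]
            if na < 2 or nb < 2:
                raise ValueError(f"group size < 2 in pair ({a}, {b})")
            se2 = va / na + vb / nb
            t = (ma - mb) / np.sqrt(se2)
            df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
            p = float(stats.studentized_range.sf(abs(t) * np.sqrt(2.0), k, df))
            rows.append(
                {
                    "group_a": a,
                    "group_b": b,
                    "mean_diff": float(ma - mb),
                    "t": float(t),
                    "df": float(df),
                    "p": p,
                }
            )
    return pd.DataFrame(rows)


def run_group_tests(
    samples: Mapping[str, Sequence[float]], design: str = "independent"
) -> dict:
    """Group comparison report: descriptives, t-tests, ANOVA + Games–Howell,
    Kruskal–Wallis.

    ``design='paired'`` uses paired t-tests (groups must be equal length).
    Two groups get a t-test; three or more also get one-way ANOVA with
    Games–Howell post hoc and a Kruskal–Wallis test.
    """
    names = sorted(samples)
    if len(names) < 2:
        raise ValueError("need at least two groups")
    arrays = {g: np.asarray(samples[g], dtype=float) for g in names}
    for g, arr in arrays.items():
        if len(arr) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")
    report: dict = {
        "design": design,
        "descriptives": {
            g: {
                "n": int(len(a)),
                "mean": float(a.mean()),
                "se": float(a.std(ddof=1) / np.sqrt(len(a))),
            }
            for g, a in arrays.items()
        },
    }
    pair_rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = arrays[names[i]], arrays[names[j]]
            if design == "paired":
                if len(a) != len(b):
                    raise ValueError("paired design requires equal group sizes")
                if np.allclose(a, b):
                    t, p = 0.0, 1.0  # identical pairs: no evidence of a difference
                else:
                    t, p = stats.ttest_rel(a, b)
                df = len(a) - 1
            else:
                t, p = stats.ttest_ind(a, b, equal_var=False)
                va, vb = a.var(ddof=1), b.var(ddof=1)
                na, nb = len(a), len(b)
                se2 = va / na + vb / nb
                df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
            pair_rows.append(
                {
                    "group_a": names[i],
                    "group_b": names[j],
                    "t": float(t),
                    "df": float(df),
                    "p": float(p),
                }
            )
    report["t_tests"] = pair_rows
    if len(names) >= 3:
        f, p = stats.f_oneway(*arrays.values())
        report["anova"] = {
            "F": float(f),
            "df_between": len(names) - 1,
            "df_within": int(sum(len(a) for a in arrays.values()) - len(names)),
            "p": float(p),
        }
        report["games_howell"] = games_howell(arrays).to_dict(orient="records")
        h, p_kw = stats.kruskal(*arrays.values())
        report["kruskal_wallis"] = {"H": float(h), "df": len(names) - 1, "p": float(p_kw)}
    return report
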