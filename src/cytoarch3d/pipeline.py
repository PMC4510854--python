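"""Pipeline orchestration: simulate → frame → stereology → sheets → stats → tomo.

A run is driven by a single JSON config (layered over defaults) plus a seed
and an output directory.  Every stage writes its tables/JSON into the run
directory; a manifest records the package version, the config (and its
hash) and the seed, so identical config+seed reproduces identical outputs
byte for byte.  A stage failure aborts the run with the failing stage named
and leaves the partial outputs plus a failure marker behind.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .cell_geometry import build_cell_frame
from .io_formats import LabelVolume, read_label_volume, write_label_volume, write_measurements
from .sheet_assembly import assemble_sheets, sheet_table
from .spatial_stats import (
    mito_density_per_type,
    mito_membrane_association,
    ribbon_to_sheet_distances,
    terminal_distribution,
)
from .stereology import classify_points, make_point_grid, volume_fraction
from .synthetic_data import (
    CellGenParams,
    TomoGenParams,
    generate_cell_volume,
    generate_tomogram_volume,
)
from .tomo_links import compare_contexts, measure_links, vesicle_diameters

__all__ = ["RunConfig", "run_pipeline", "make_report", "DEFAULT_STAGES"]

DEFAULT_STAGES = ("simulate", "frame", "stereology", "sheets", "stats", "tomo")

_DEFAULTS = {
    "stages": list(DEFAULT_STAGES),
    "cell": {"preset": "small", "overrides": {}, "input": None},
    "tomo": {"scale": 1.0, "overrides": {}, "input": None},
    "frame": {"flat_faces": "pillar", "bands_um": None},
    "stereology": {"mode": "whole", "spacing_nm": [200.0, 200.0, 200.0], "offset": "sur"},
    "sheets": {"overlap_min": 1, "area_mode": "sheet_face", "tube_radius_nm": 50.0},
    "stats": {"gap_threshold_nm": None},
    "tomo_links": {"ribbon_context_nm": 100.0},
}


@dataclass
class RunConfig:
    """Validated run configuration (defaults ← file ← explicit overrides)."""

    seed: int | None
    out_dir: Path
    options: dict = field(default_factory=dict)

    @staticmethod
    def load(
        path: str | Path | None,
        out_dir: str | Path,
        seed: int | None = None,
        overrides: dict | None = None,
    ) -> "RunConfig":
        cfg = json.loads(json.dumps(_DEFAULTS))  # deep copy
        if path is not None:
            user = json.loads(Path(path).read_text())
            for key, val in user.items():
                if isinstance(val, dict) and isinstance(cfg.get(key), dict):
                    cfg[key].update(val)
                else:
                    cfg[key] = val
        if overrides:
            for key, val in overrides.items():
                if isinstance(val, dict) and isinstance(cfg.get(key), dict):
                    cfg[key].update(val)
                else:
                    cfg[key] = val
        if seed is None:
            seed = cfg.get("seed")
        stochastic = "simulate" in cfg["stages"] or cfg["stereology"]["offset"] == "sur"
        if stochastic and seed is None:
            raise ValueError(
                "config error: a seed is mandatory when any stochastic stage "
                "(simulate, SUR stereology offsets) is enabled"
            )
        unknown = set(cfg["stages"]) - set(DEFAULT_STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}; allowed: {DEFAULT_STAGES}")
        return RunConfig(seed=seed, out_dir=Path(out_dir), options=cfg)

    def hash(self) -> str:
        payload = json.dumps({"options": self.options, "seed": self.seed}, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _json_dump(obj, path: Path):
    path.write_text(json.dumps(obj, indent=1, sort_keys=True, default=_coerce) + "\n")


def _coerce(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, Path):
        return str(o)
    raise TypeError(f"not JSON-serializable: {type(o)}")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in dependency order; return the manifest."""
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    (out / "FAILED").unlink(missing_ok=True)
    opts = config.options
    stages = list(opts["stages"])
    manifest = {
        "package": "cytoarch3d",
        "version": __version__,
        "seed": config.seed,
        "config": opts,
        "config_hash": config.hash(),
        "stages": {},
    }
    state: dict = {}
    order = [s for s in DEFAULT_STAGES if s in stages]
    for stage in order:
        try:
            _STAGE_FNS[stage](config, state, out)
            manifest["stages"][stage] = "ok"
        except Exception as exc:
            manifest["stages"][stage] = f"failed: {exc}"
            _json_dump(manifest, out / "manifest.json")
            (out / "FAILED").write_text(f"stage {stage}: {exc}\n")
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    _json_dump(manifest, out / "manifest.json")
    return manifest


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def _stage_simulate(config: RunConfig, state: dict, out: Path):
    opts = config.options
    cell_cfg = opts["cell"]
    if cell_cfg.get("input") is None:
        preset = cell_cfg.get("preset", "small")
        maker = {
            "small": CellGenParams.small,
            "medium": CellGenParams.medium,
            "shape_only": CellGenParams.shape_only,
            "full": lambda seed, **kw: CellGenParams(seed=seed, **kw),
        }[preset]
        params = maker(seed=int(config.seed), **cell_cfg.get("overrides", {}))
        vol, truth = generate_cell_volume(params)
        write_label_volume(vol, out / "cell.tif")
        truth.to_json(out / "cell_truth.json")
        state["cell"] = vol
        state["cell_truth"] = truth
    tomo_cfg = opts["tomo"]
    if tomo_cfg.get("input") is None and "tomo" in opts["stages"]:
        tp = TomoGenParams.scaled(
            float(tomo_cfg.get("scale", 1.0)),
            seed=int(config.seed) + 1,
            **tomo_cfg.get("overrides", {}),
        )
        tvol, ttruth = generate_tomogram_volume(tp)
        write_label_volume(tvol, out / "tomogram.tif")
        ttruth.to_json(out / "tomogram_truth.json")
        state["tomo"] = tvol
        state["tomo_truth"] = ttruth


def _cell_volume(config: RunConfig, state: dict) -> LabelVolume:
    if "cell" not in state:
        path = config.options["cell"].get("input")
        if path is None:
            raise RuntimeError("no cell volume: enable the simulate stage or set cell.input")
        state["cell"] = read_label_volume(path)
    return state["cell"]


def _stage_frame(config: RunConfig, state: dict, out: Path):
    vol = _cell_volume(config, state)
    fcfg = config.options["frame"]
    bands = fcfg.get("bands_um")
    frame = build_cell_frame(
        vol,
        flat_faces=fcfg.get("flat_faces", "pillar"),
        bands_um=tuple(map(tuple, bands)) if bands else None,
    )
    state["frame"] = frame
    payload = {
        "flat_sign": frame.flat_sign,
        "flat_faces": frame.flat_faces,
        "perinuclear_z": list(frame.perinuclear_z),
        "centre_line_nm": [
            {"z_index": iz, "cx_nm": frame.centre_line[iz, 0], "cy_nm": frame.centre_line[iz, 1]}
            for iz in range(len(frame.centre_line))
            if np.isfinite(frame.centre_line[iz, 0])
        ],
    }
    if frame.flatness is not None:
        payload["flatness"] = {
            "bands_um": [list(b) for b in frame.flatness.bands_um],
            "deviation_nm": frame.flatness.deviation_nm,
            "tied": frame.flatness.tied,
            "neck_y_nm": frame.flatness.neck_y_nm,
        }
    _json_dump(payload, out / "frame.json")


def _stage_stereology(config: RunConfig, state: dict, out: Path):
    vol = _cell_volume(config, state)
    frame = state.get("frame")
    if frame is None:
        raise RuntimeError("stereology requires the frame stage")
    scfg = config.options["stereology"]
    rng = np.random.default_rng(None if config.seed is None else int(config.seed) + 2)
    mode = scfg.get("mode", "whole")
    kwargs = {}
    if mode == "partial":
        kwargs["z_window"] = frame.perinuclear_z
        spacing = list(scfg.get("spacing_nm"))
        spacing[2] = vol.voxel_size[2]
        kwargs["spacing_nm"] = tuple(spacing)
    else:
        kwargs["spacing_nm"] = tuple(scfg.get("spacing_nm"))
    grid = make_point_grid(
        frame.infranuclear,
        vol.voxel_size,
        mode=mode,
        offset=scfg.get("offset", "sur"),
        rng=rng,
        **kwargs,
    )
    grid = classify_points(grid, vol, frame)
    idx = vol.nm_to_index(grid.points_nm)
    in_region = frame.infranuclear[idx[:, 0], idx[:, 1], idx[:, 2]]
    rows = []
    for axis in ("flat_round", "ant_post"):
        for hemi in sorted(set(grid.hemisphere_tags[axis])):
            sel = in_region & (grid.hemisphere_tags[axis] == hemi)
            est = volume_fraction(grid, region=sel, region_name=hemi)
            rows.append(
                {
                    "cell_id": 0,
                    "region": est.region,
                    "axis": axis,
                    "n": est.n_points,
                    "hits_count": est.n_hits,
                    "fraction_frac": est.fraction,
                    "se_frac": est.se,
                }
            )
    state["stereology"] = rows
    write_measurements(rows, out / "stereology.csv")


def _stage_sheets(config: RunConfig, state: dict, out: Path):
    vol = _cell_volume(config, state)
    scfg = config.options["sheets"]
    sheets, stats, bnd, degenerate = assemble_sheets(
        vol,
        overlap_min=int(scfg.get("overlap_min", 1)),
        area_mode=scfg.get("area_mode", "sheet_face"),
        tube_radius_nm=float(scfg.get("tube_radius_nm", 50.0)),
    )
    state["sheets"] = sheets
    table = sheet_table(sheets).rename(columns={"area_um2": "area_um2"})
    table.insert(0, "cell_id", 0)
    rows = table.rename(columns={"id": "object_id"}).to_dict(orient="records")
    write_measurements(rows, out / "sheets.csv")
    payload = {
        "n_sheets": len(sheets),
        "degenerate": degenerate,
        "boundaries": None
        if bnd is None
        else {
            "t1_threshold_um2": bnd.t1_threshold_um2,
            "t2_threshold_um2": bnd.t2_threshold_um2,
            "method": bnd.method,
        },
        "per_type": None if stats is None else stats.to_dict(orient="records"),
    }
    state["sheet_stats"] = payload
    _json_dump(payload, out / "sheet_stats.json")


def _stage_stats(config: RunConfig, state: dict, out: Path):
    vol = _cell_volume(config, state)
    frame = state.get("frame")
    sheets = state.get("sheets")
    if frame is None or sheets is None:
        raise RuntimeError("stats requires the frame and sheets stages")
    gap = config.options["stats"].get("gap_threshold_nm")
    recs, assoc_summary = mito_membrane_association(vol, sheets, gap_threshold_nm=gap)
    rows = [
        {
            "cell_id": 0,
            "object_id": r.mito_id,
            "distance_nm": r.distance_nm,
            "gap_nm": r.gap_nm,
            "associated": r.associated,
            "n_types": len(r.types_touched),
        }
        for r in recs
    ]
    write_measurements(rows, out / "mito_association.csv")
    type_areas = {}
    for sh in sheets:
        if sh.class_label is not None:
            type_areas[sh.class_label] = type_areas.get(sh.class_label, 0.0) + sh.area_um2
    density = mito_density_per_type(recs, type_areas) if type_areas else None
    drecs, dtable = ribbon_to_sheet_distances(vol, sheets)
    drows = [
        {
            "cell_id": 0,
            "object_id": r.ribbon_id,
            **{f"type{t}_nm": d for t, d in sorted(r.distance_by_type_nm.items())},
            "nearest_type": r.nearest_type,
        }
        for r in drecs
    ]
    write_measurements(drows, out / "ribbon_distances.csv")
    trecs, tsummary = terminal_distribution(vol, frame)
    trows = [
        {
            "cell_id": 0,
            "object_id": r.terminal_id,
            "hemisphere_flat_round": r.hemisphere_flat_round,
            "hemisphere_mod_pillar": r.hemisphere_mod_pillar,
            "longitudinal_nm": r.longitudinal_nm,
        }
        for r in trecs
    ]
    write_measurements(trows, out / "terminals.csv")
    summary = {
        "association": assoc_summary,
        "terminals": tsummary,
        "ribbon_distance_by_type": dtable.to_dict(orient="records"),
        "mito_density_per_type": None if density is None else density.to_dict(orient="records"),
    }
    state["stats"] = summary
    _json_dump(summary, out / "stats_summary.json")


def _stage_tomo(config: RunConfig, state: dict, out: Path):
    if "tomo" not in state:
        path = config.options["tomo"].get("input")
        if path is None:
            raise RuntimeError("no tomogram volume: enable simulate or set tomo.input")
        state["tomo"] = read_label_volume(path)
    tvol = state["tomo"]
    ctx_nm = float(config.options["tomo_links"].get("ribbon_context_nm", 100.0))
    links = measure_links(tvol, ribbon_context_nm=ctx_nm)
    rows = [
        {
            "object_id": l.link_id,
            "context": l.context if l.context else "unclassified",
            "length_nm": l.length_nm,
            "straight_length_nm": l.straight_length_nm,
            "attached_both_ends": l.attached_both_ends,
        }
        for l in links
    ]
    write_measurements(rows, out / "links.csv")
    ves = vesicle_diameters(tvol)
    vrows = [
        {
            "object_id": v.vesicle_id,
            "diameter_nm": v.diameter_nm,
            "location": v.location,
            "unreliable": v.unreliable,
        }
        for v in ves
    ]
    write_measurements(vrows, out / "vesicles.csv")
    rep = compare_contexts(links)
    payload = {
        "per_context": rep["summary"].to_dict(orient="records"),
        "shorter_pairs": [[a, b, p] for a, b, p in rep["shorter_pairs"]],
        "vesicle_diameter_by_location": {
            loc: {
                "n": sum(1 for v in ves if v.location == loc),
                "mean_nm": float(np.mean([v.diameter_nm for v in ves if v.location == loc]))
                if any(v.location == loc for v in ves)
                else None,
            }
            for loc in ("at_RER", "at_ribbon", "free")
        },
    }
    state["tomo_report"] = payload
    _json_dump(payload, out / "tomo_summary.json")


_STAGE_FNS = {
    "simulate": _stage_simulate,
    "frame": _stage_frame,
    "stereology": _stage_stereology,
    "sheets": _stage_sheets,
    "stats": _stage_stats,
    "tomo": _stage_tomo,
}


def make_report(run_dir: str | Path) -> dict:
    """Assemble a per-run summary mirroring the standard reporting shape.

    Reads the stage outputs present in ``run_dir`` (an incomplete run with a
    FAILED marker or no manifest is an error) and writes ``report.json``.
    """
    run_dir = Path(run_dir)
    manifest_path = run_dir / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest in {run_dir}: not a completed run")
    if (run_dir / "FAILED").exists():
        raise RuntimeError(f"run in {run_dir} failed: {(run_dir / 'FAILED').read_text().strip()}")
    manifest = json.loads(manifest_path.read_text())
    report: dict = {"config_hash": manifest["config_hash"], "seed": manifest["seed"]}
    for name, fname in (
        ("stereology", "stereology.csv"),
        ("sheet_stats", "sheet_stats.json"),
        ("stats", "stats_summary.json"),
        ("tomo", "tomo_summary.json"),
    ):
        f = run_dir / fname
        if f.exists():
            if fname.endswith(".json"):
                report[name] = json.loads(f.read_text())
            else:
                import pandas as pd

                report[name] = pd.read_csv(f).to_dict(orient="records")
    _json_dump(report, run_dir / "report.json")
    return report
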