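"""Label-volume, geometry-model and measurement-table I/O.

Conventions enforced throughout the package:

* voxel arrays are indexed ``(z, y, x)`` with ``z`` the sectioning axis;
* ``voxel_size`` is given as ``(x, y, z)`` in nanometres;
* all public coordinates are 0-based, voxel-centre, physical nanometres —
  voxel indices never cross module boundaries;
* a label volume is never read without an explicit voxel size (TIFF needs a
  JSON sidecar; MRC carries it in the header).

Supported on-disk formats: multi-page TIFF + JSON sidecar, MRC (2014-style
1024-byte header, modes 0/1/2/6), JSON geometry models, CSV measurement
tables with unit-annotated column names.
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "SEMANTIC_CLASSES",
    "LabelVolume",
    "GeometryModel",
    "GeometryObject",
    "read_label_volume",
    "write_label_volume",
    "read_geometry_model",
    "write_geometry_model",
    "write_measurements",
    "read_measurements",
]

#: semantic classes a label may map to
SEMANTIC_CLASSES = frozenset(
    {
        "background",
        "cell",
        "nucleus",
        "membrane",
        "mitochondrion",
        "ribbon",
        "terminal",
        "vesicle",
        "tether",
    }
)


class VolumeIOError(RuntimeError):
    """Raised on malformed or metadata-incomplete volume files."""


@dataclass
class LabelVolume:
    """A segmented 3D volume: integer labels plus physical metadata.

    Parameters
    ----------
    voxels
        3D integer array indexed ``(z, y, x)``.
    voxel_size
        ``(x, y, z)`` voxel edge lengths in nm; strictly positive.
    label_table
        Maps every non-zero label value to a semantic class from
        :data:`SEMANTIC_CLASSES`.
    """

    voxels: np.ndarray
    voxel_size: tuple[float, float, float]
    label_table: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"voxels must be 3D (z,y,x), got ndim={self.voxels.ndim}")
        if not np.issubdtype(self.voxels.dtype, np.integer):
            raise ValueError("voxels must be an integer label array")
        vs = tuple(float(v) for v in self.voxel_size)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValueError(f"voxel_size must be 3 positive nm values, got {self.voxel_size}")
        self.voxel_size = vs
        self.label_table = {int(k): str(v) for k, v in self.label_table.items()}
        bad = set(self.label_table.values()) - SEMANTIC_CLASSES
        if bad:
            raise ValueError(f"unknown semantic classes in label_table: {sorted(bad)}")
        present = np.unique(self.voxels)
        missing = [int(v) for v in present if v != 0 and int(v) not in self.label_table]
        if missing:
            raise ValueError(f"labels present in voxels but absent from label_table: {missing}")

    # -- physical geometry helpers -------------------------------------------------

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.voxels.shape)  # type: ignore[return-value]

    @property
    def sampling_zyx(self) -> tuple[float, float, float]:
        """Voxel size reordered to array-axis order (z, y, x), nm."""
        sx, sy, sz = self.voxel_size
        return (sz, sy, sx)

    def extent_nm(self) -> tuple[float, float, float]:
        """Physical extent (x, y, z) of the volume in nm."""
        nz, ny, nx = self.voxels.shape
        sx, sy, sz = self.voxel_size
        return (nx * sx, ny * sy, nz * sz)

    def mask(self, semantic_class: str) -> np.ndarray:
        """Boolean mask of all voxels whose label maps to *semantic_class*."""
        labels = [lab for lab, cls in self.label_table.items() if cls == semantic_class]
        if not labels:
            return np.zeros(self.voxels.shape, dtype=bool)
        return np.isin(self.voxels, labels)

    def labels_of(self, semantic_class: str) -> list[int]:
        return sorted(lab for lab, cls in self.label_table.items() if cls == semantic_class)

    def index_to_nm(self, zyx: np.ndarray) -> np.ndarray:
        """Convert ``(n, 3)`` voxel indices (z,y,x) to nm coordinates (x,y,z)."""
        zyx = np.atleast_2d(np.asarray(zyx, dtype=float))
        sx, sy, sz = self.voxel_size
        return np.column_stack([zyx[:, 2] * sx, zyx[:, 1] * sy, zyx[:, 0] * sz])

    def nm_to_index(self, xyz_nm: np.ndarray) -> np.ndarray:
        """Convert nm coordinates (x,y,z) to nearest voxel indices (z,y,x)."""
        xyz = np.atleast_2d(np.asarray(xyz_nm, dtype=float))
        sx, sy, sz = self.voxel_size
        idx = np.column_stack(
            [np.rint(xyz[:, 2] / sz), np.rint(xyz[:, 1] / sy), np.rint(xyz[:, 0] / sx)]
        ).astype(np.int64)
        return idx


# ---------------------------------------------------------------------------
# TIFF + sidecar
# ---------------------------------------------------------------------------


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_label_volume(volume: LabelVolume, path: str | Path) -> Path:
    """Write a label volume to TIFF+sidecar (``.tif``) or MRC (``.mrc``).

    Returns the path written.  TIFF output carries voxel size and the label
    table in a JSON sidecar next to the image file; MRC stores the voxel size
    in the header and the label table in a sidecar as well (labels are not
    expressible in an MRC header).
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, volume.voxels, photometric="minisblack")
    elif suffix == ".mrc":
        _write_mrc(path, volume.voxels, volume.voxel_size)
    else:
        raise VolumeIOError(f"unknown volume format {suffix!r} (use .tif/.tiff or .mrc)")
    sidecar = _sidecar_path(path)
    meta = {
        "voxel_size_nm": list(volume.voxel_size),
        "axes": "zyx",
        "label_table": {str(k): v for k, v in sorted(volume.label_table.items())},
    }
    sidecar.write_text(json.dumps(meta, indent=1, sort_keys=True) + "\n")
    return path


def read_label_volume(path: str | Path, sidecar: str | Path | None = None) -> LabelVolume:
    """Read a label volume written by :func:`write_label_volume`.

    Voxel size must be recoverable: from the sidecar for TIFF, from the header
    (or sidecar) for MRC.  A missing voxel size is an error, never a silent
    default.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    sidecar = Path(sidecar) if sidecar is not None else _sidecar_path(path)
    meta: dict = {}
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())

    if suffix in (".tif", ".tiff"):
        voxels = tifffile.imread(path)
        if voxels.ndim == 2:
            voxels = voxels[None]
        if "voxel_size_nm" not in meta:
            raise VolumeIOError(
                f"voxel size missing: TIFF {path.name} has no sidecar {sidecar.name} "
                "with a 'voxel_size_nm' entry"
            )
        voxel_size = tuple(meta["voxel_size_nm"])
    elif suffix == ".mrc":
        voxels, header_vs = _read_mrc(path)
        voxel_size = tuple(meta.get("voxel_size_nm", header_vs or ()))
        if not voxel_size or any(v <= 0 for v in voxel_size):
            raise VolumeIOError(f"voxel size missing from MRC header and sidecar for {path.name}")
    else:
        raise VolumeIOError(f"unknown volume format {suffix!r} (use .tif/.tiff or .mrc)")

    label_table = {int(k): v for k, v in meta.get("label_table", {}).items()}
    if not label_table:
        # fall back to identity-less table: every non-zero label must be declared
        present = [int(v) for v in np.unique(voxels) if v != 0]
        if present:
            raise VolumeIOError(
                f"label table missing for {path.name}: labels {present} are undeclared"
            )
    return LabelVolume(voxels=voxels, voxel_size=voxel_size, label_table=label_table)


# ---------------------------------------------------------------------------
# Minimal MRC (2014 header layout, no extended header)
# ---------------------------------------------------------------------------

_MRC_MODES = {0: np.int8, 1: np.int16, 2: np.float32, 6: np.uint16}
_MRC_MODE_OF = {np.dtype(v): k for k, v in _MRC_MODES.items()}


def _write_mrc(path: Path, voxels: np.ndarray, voxel_size: Sequence[float]) -> None:
    dtype = voxels.dtype
    if np.dtype(dtype) not in _MRC_MODE_OF:
        if np.issubdtype(dtype, np.integer) and voxels.max(initial=0) < 2**15:
            voxels = voxels.astype(np.int16)
        else:
            raise VolumeIOError(f"dtype {dtype} not representable in MRC modes 0/1/2/6")
    mode = _MRC_MODE_OF[np.dtype(voxels.dtype)]
    nz, ny, nx = voxels.shape
    sx, sy, sz = voxel_size
    header = bytearray(1024)
    # word 1-3: nx ny nz (columns fastest); 4: mode; 8-10: mx my mz
    struct.pack_into("<3i", header, 0, nx, ny, nz)
    struct.pack_into("<i", header, 12, mode)
    struct.pack_into("<3i", header, 28, nx, ny, nz)
    # cella: cell dimensions in Å (nm * 10)
    struct.pack_into("<3f", header, 40, nx * sx * 10.0, ny * sy * 10.0, nz * sz * 10.0)
    struct.pack_into("<3i", header, 64, 1, 2, 3)  # mapc/mapr/maps
    dmin, dmax = float(voxels.min()), float(voxels.max())
    struct.pack_into("<3f", header, 76, dmin, dmax, float(voxels.mean()))
    header[208:212] = b"MAP "
    header[212:216] = b"\x44\x44\x00\x00"  # little-endian machine stamp
    with open(path, "wb") as fh:
        fh.write(bytes(header))
        fh.write(np.ascontiguousarray(voxels).tobytes())


def _read_mrc(path: Path) -> tuple[np.ndarray, tuple[float, float, float] | None]:
    raw = path.read_bytes()
    if len(raw) < 1024:
        raise VolumeIOError(f"{path.name}: truncated MRC header")
    nx, ny, nz = struct.unpack_from("<3i", raw, 0)
    (mode,) = struct.unpack_from("<i", raw, 12)
    mx, my, mz = struct.unpack_from("<3i", raw, 28)
    cx, cy, cz = struct.unpack_from("<3f", raw, 40)
    if mode not in _MRC_MODES:
        raise VolumeIOError(f"{path.name}: unsupported MRC mode {mode}")
    dtype = np.dtype(_MRC_MODES[mode]).newbyteorder("<")
    n = nx * ny * nz
    data = np.frombuffer(raw, dtype=dtype, count=n, offset=1024)
    voxels = data.reshape(nz, ny, nx).astype(_MRC_MODES[mode])
    voxel_size = None
    if mx > 0 and my > 0 and mz > 0 and cx > 0 and cy > 0 and cz > 0:
        # cella is in Å; convert to nm per voxel
        voxel_size = (cx / mx / 10.0, cy / my / 10.0, cz / mz / 10.0)
    return voxels, voxel_size


# ---------------------------------------------------------------------------
# Geometry models (JSON interchange; spheres, polylines, tubes)
# ---------------------------------------------------------------------------

_GEOMETRY_KINDS = ("sphere", "polyline", "tube")

#: default tube radius, nm — half the 100 nm section-to-section spacing of the
#: acquisition this package models (membrane strands modelled as 50 nm tubes)
DEFAULT_TUBE_RADIUS_NM = 50.0


@dataclass
class GeometryObject:
    """One geometric primitive in physical nm coordinates (x, y, z)."""

    kind: str
    id: int
    coordinates: np.ndarray  # (n, 3) nm; (1, 3) for spheres
    radius: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in _GEOMETRY_KINDS:
            raise ValueError(f"kind must be one of {_GEOMETRY_KINDS}, got {self.kind!r}")
        self.coordinates = np.atleast_2d(np.asarray(self.coordinates, dtype=float))
        if self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must be (n, 3) nm")
        if self.kind == "sphere" and (self.radius is None or self.radius <= 0):
            raise ValueError("sphere requires a positive radius")
        if self.kind == "tube" and self.radius is None:
            self.radius = DEFAULT_TUBE_RADIUS_NM


@dataclass
class GeometryModel:
    objects: list[GeometryObject] = field(default_factory=list)


def write_geometry_model(model: GeometryModel, path: str | Path) -> Path:
    path = Path(path)
    payload = {
        "objects": [
            {
                "kind": o.kind,
                "id": int(o.id),
                "coordinates_nm": np.asarray(o.coordinates).tolist(),
                "radius_nm": None if o.radius is None else float(o.radius),
            }
            for o in model.objects
        ]
    }
    path.write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")
    return path


def read_geometry_model(path: str | Path) -> GeometryModel:
    payload = json.loads(Path(path).read_text())
    objects = [
        GeometryObject(
            kind=o["kind"],
            id=int(o["id"]),
            coordinates=np.asarray(o["coordinates_nm"], dtype=float),
            radius=o.get("radius_nm"),
        )
        for o in payload["objects"]
    ]
    return GeometryModel(objects=objects)


# ---------------------------------------------------------------------------
# Measurement tables
# ---------------------------------------------------------------------------

_UNIT_SUFFIXES = ("_nm", "_um", "_um2", "_um3", "_nm2", "_nm3", "_per_um2", "_frac", "_count", "_p")
_SORT_KEYS = ("cell_id", "object_id", "id")
#: unit-less by nature: identifiers, indices and categorical codes
_UNITLESS_COLUMNS = {"id", "seed", "z", "n", "class", "type", "nearest_type",
                     "z_min", "z_max", "n_strands", "n_types"}


def write_measurements(
    records: Sequence[Mapping], path: str | Path, columns: Sequence[str] | None = None
) -> Path:
    """Write measurement records as a deterministic, unit-annotated CSV.

    Every numeric column name must end in a unit suffix (``_nm``, ``_um2``,
    ``_frac``, ``_count``, ``_p`` …); unit-less numeric columns are refused so
    no quantity leaves the package without its unit.  Rows are sorted by
    (cell_id, object_id, id) where present so re-export is byte-identical.
    """
    path = Path(path)
    df = pd.DataFrame(list(records), columns=columns)
    for col in df.columns:
        if pd.api.types.is_numeric_dtype(df[col]) and not df[col].isna().all():
            if pd.api.types.is_bool_dtype(df[col]):
                continue
            if col.endswith("_id") or col in _UNITLESS_COLUMNS:
                continue
            if not any(col.endswith(sfx) for sfx in _UNIT_SUFFIXES):
                raise ValueError(
                    f"numeric column {col!r} has no unit suffix; annotate units "
                    f"(one of {_UNIT_SUFFIXES}) before export"
                )
    sort_cols = [c for c in _SORT_KEYS if c in df.columns]
    if sort_cols and len(df):
        df = df.sort_values(sort_cols, kind="mergesort").reset_index(drop=True)
    df.to_csv(path, index=False, lineterminator="\n", float_format="%.6g")
    return path


def read_measurements(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
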