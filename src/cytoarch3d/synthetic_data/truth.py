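"""Ground-truth bookkeeping for generated phantoms."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["GroundTruth"]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


@dataclass
class GroundTruth:
    """Planted truth for one generated volume.

    ``tables`` holds per-object record lists (keys like ``sheets``,
    ``mitochondria``, ``ribbons``, ``terminals``, ``links``, ``vesicles``,
    ``centre_line``); ``summary`` holds scalar truths (hemisphere fractions,
    association rate, flatness per band, …); ``params`` echoes the generator
    configuration so a truth file alone identifies its provenance.
    """

    kind: str
    params: dict
    tables: dict[str, list[dict]] = field(default_factory=dict)
    summary: dict = field(default_factory=dict)

    def table(self, name: str) -> pd.DataFrame:
        return pd.DataFrame(self.tables.get(name, []))

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "kind": self.kind,
            "params": _jsonable(self.params),
            "tables": _jsonable(self.tables),
            "summary": _jsonable(self.summary),
        }
        path.write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")
        return path

    @staticmethod
    def from_json(path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        return GroundTruth(
            kind=payload["kind"],
            params=payload["params"],
            tables=payload["tables"],
            summary=payload["summary"],
        )
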