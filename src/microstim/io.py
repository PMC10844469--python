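"""Per-cell table and results I/O with provenance headers.

Every CSV written by the pipeline starts with ``#``-prefixed comment lines
recording the package version, the seed, and a hash of the configuration
that produced it, so any table can be traced back to a reproducible run.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, is_dataclass

import pandas as pd

from . import __version__
from .synthetic import CELL_COLUMNS

__all__ = ["write_cells", "read_cells", "write_table", "config_hash", "CELL_COLUMNS"]


def config_hash(config) -> str:
    """Short stable hash of a (nested) configuration object."""

    def canon(obj):
        if is_dataclass(obj) and not isinstance(obj, type):
            return {k: canon(v) for k, v in asdict(obj).items()}
        if isinstance(obj, dict):
            return {k: canon(v) for k, v in sorted(obj.items())}
        if isinstance(obj, (list, tuple)):
            return [canon(v) for v in obj]
        return obj

    payload = json.dumps(canon(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _header(meta: dict | None) -> str:
    lines = [f"# microstim {__version__}"]
    for key, value in (meta or {}).items():
        lines.append(f"# {key}: {value}")
    return "\n".join(lines) + "\n"


def write_table(df: pd.DataFrame, path, meta: dict | None = None) -> None:
    """Write a tidy CSV with a provenance comment header."""
    with open(path, "w") as fh:
        fh.write(_header(meta))
        df.to_csv(fh, index=False)


def write_cells(cells: pd.DataFrame, path, meta: dict | None = None) -> None:
    """Write the per-cell table in the canonical column order."""
    extra = [c for c in cells.columns if c not in CELL_COLUMNS]
    write_table(cells[CELL_COLUMNS + extra], path, meta)


def read_cells(path) -> pd.DataFrame:
    """Read a per-cell CSV, skipping provenance comments."""
    df = pd.read_csv(path, comment="#")
    missing = [c for c in CELL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"per-cell table missing columns: {missing}")
    for col in ("ground_truth", "called"):
        df[col] = df[col].astype("boolean")
    df["n_neighbors"] = df["n_neighbors"].astype("Int64")
    df["experiment_id"] = df["experiment_id"].fillna("").astype(str)
    return df
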