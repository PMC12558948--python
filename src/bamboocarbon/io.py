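"""CSV interchange for footprint and plot tables.

Footprint CSV schema: record_id, sensor, x, y, elevation, then one column
per parameter or quality flag. Plot CSV schema: plot_id, x, y, radius_m,
dbh_list (semicolon-separated cm values), agc_mg_ha. Files may start with
``#``-prefixed metadata lines (config hash, seed) which readers skip; the
writers embed them so every artifact records its provenance.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .sampling import CORE_COLUMNS

PLOT_COLUMNS = ("plot_id", "x", "y", "radius_m", "dbh_list", "agc_mg_ha")


class SchemaError(ValueError):
    pass


def config_hash(config_dict: dict) -> str:
    """Stable short hash of a JSON-serialisable configuration."""
    blob = json.dumps(config_dict, sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _write_csv(table: pd.DataFrame, path, metadata: dict | None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for key, val in (metadata or {}).items():
            fh.write(f"# {key}={val}\n")
        table.to_csv(fh, index=False, lineterminator="\n")


def _read_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def _require(table: pd.DataFrame, columns, path) -> None:
    missing = [c for c in columns if c not in table.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")


def _check_numeric(table: pd.DataFrame, columns, path) -> pd.DataFrame:
    for col in columns:
        converted = pd.to_numeric(table[col], errors="coerce")
        bad = converted.isna() & table[col].notna()
        if bad.any():
            row = int(np.argmax(bad.to_numpy()))
            raise SchemaError(
                f"{path}: malformed numeric value in column {col!r}, "
                f"row {row} ({table[col].iloc[row]!r})")
        table[col] = converted
    return table


def write_footprint_csv(table: pd.DataFrame, path,
                        metadata: dict | None = None) -> None:
    _require(table, CORE_COLUMNS, path)
    _write_csv(table, path, metadata)


def read_footprint_csv(path) -> pd.DataFrame:
    table = _read_csv(path)
    _require(table, CORE_COLUMNS, path)
    numeric = [c for c in table.columns if c not in ("sensor",)]
    return _check_numeric(table, numeric, path)


def write_plot_csv(table: pd.DataFrame, path,
                   metadata: dict | None = None) -> None:
    _require(table, PLOT_COLUMNS, path)
    _write_csv(table, path, metadata)


def read_plot_csv(path) -> pd.DataFrame:
    table = _read_csv(path)
    _require(table, PLOT_COLUMNS, path)
    numeric = [c for c in PLOT_COLUMNS if c not in ("dbh_list",)]
    table = _check_numeric(table, numeric, path)
    table["dbh_list"] = table["dbh_list"].fillna("")
    return table


def parse_dbh_list(cell: str) -> np.ndarray:
    """Decode a semicolon-separated DBH cell into a float array."""
    cell = str(cell).strip()
    if not cell:
        return np.zeros(0)
    return np.array([float(tok) for tok in cell.split(";")])
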