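"""Tabular I/O for well-level colony counts and plate layouts.

Two flat-file dialects are shared by every stage:

``wells.csv`` — one row per well:
    run_id, plate_id, well_id, target, sirna_id, dose, cells_plated, colonies

``layout.csv`` — one row per well position:
    well_id, target, sirna_id, role        (role in {sample, nt_control, pos_control})

CSV is the default; files ending in ``.tsv``/``.tab`` are tab-separated.
Doses are decimal Gy, well ids zero-padded ("A01"), counts non-negative
integers.  Control roles come from the layout, never from target names.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

WELL_COLUMNS = ["run_id", "plate_id", "well_id", "target", "sirna_id",
                "dose", "cells_plated", "colonies"]
LAYOUT_COLUMNS = ["well_id", "target", "sirna_id", "role"]
ROLES = {"sample", "nt_control", "pos_control"}


def _sep(path) -> str:
    return "\t" if Path(path).suffix.lower() in {".tsv", ".tab"} else ","


def _fail(row: int, msg: str):
    # +2: header line and 1-based numbering
    raise ValueError(f"row {row + 2}: {msg}")


def read_well_records(path, layout: pd.DataFrame | None = None) -> pd.DataFrame:
    """Read and validate a well-record table; optionally join layout roles.

    Raises ``ValueError`` naming the offending column or row for missing
    headers, negative counts, non-positive cells plated, negative doses,
    duplicate (run, plate, well) keys, or wells absent from the layout.
    """
    df = pd.read_csv(path, sep=_sep(path))
    missing = [c for c in WELL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing column(s): {', '.join(missing)}")
    df = df[list(df.columns)]
    for col, dtype in [("dose", float), ("cells_plated", "int64"), ("colonies", "int64")]:
        try:
            df[col] = df[col].astype(dtype)
        except (ValueError, TypeError) as exc:
            raise ValueError(f"column {col!r} is not numeric: {exc}") from exc
    for i, row in df.iterrows():
        if row["colonies"] < 0:
            _fail(i, f"colonies = {row['colonies']} is negative")
        if row["cells_plated"] <= 0:
            _fail(i, f"cells_plated = {row['cells_plated']} must be > 0")
        if row["dose"] < 0:
            _fail(i, f"dose = {row['dose']} is negative")
    dup = df.duplicated(subset=["run_id", "plate_id", "well_id"])
    if dup.any():
        _fail(int(dup.idxmax()), "duplicate (run_id, plate_id, well_id)")
    if layout is not None:
        unknown = set(df["well_id"]) - set(layout["well_id"])
        if unknown:
            raise ValueError(f"well(s) missing from layout: {sorted(unknown)[:5]}")
        df = df.merge(layout[["well_id", "role"]], on="well_id", how="left")
    return df


def write_well_records(table: pd.DataFrame, path) -> None:
    """Write well records in canonical column order (UTF-8, newline-terminated)."""
    missing = [c for c in WELL_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"missing column(s): {', '.join(missing)}")
    table[WELL_COLUMNS].to_csv(path, sep=_sep(path), index=False, encoding="utf-8")


def read_layout(path) -> pd.DataFrame:
    """Read a plate layout; validates roles and requires >= 1 NT control."""
    df = pd.read_csv(path, sep=_sep(path))
    missing = [c for c in LAYOUT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing column(s): {', '.join(missing)}")
    bad = set(df["role"]) - ROLES
    if bad:
        raise ValueError(f"unknown role(s): {sorted(bad)} (expected {sorted(ROLES)})")
    if not (df["role"] == "nt_control").any():
        raise ValueError("layout must contain at least one nt_control well")
    return df[LAYOUT_COLUMNS]


def write_layout(layout: pd.DataFrame, path) -> None:
    layout[LAYOUT_COLUMNS].to_csv(path, sep=_sep(path), index=False, encoding="utf-8")
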