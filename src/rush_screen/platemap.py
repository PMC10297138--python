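"""Plate-map CSV reading, validation and normalization (384-well geometry)."""

from __future__ import annotations

import re
from pathlib import Path

import pandas as pd

__all__ = ["REQUIRED_COLUMNS", "VALID_ROLES", "normalize_well_id", "read_platemap", "write_platemap"]

REQUIRED_COLUMNS = ["plate_id", "well_id", "role", "compound_id", "dose_tier", "biotin"]
VALID_ROLES = {"compound", "neg_control", "pos_control", "no_biotin", "untreated"}
VALID_TIERS = {"low", "high"}

_WELL_RE = re.compile(r"^([A-Pa-p])0*([1-9][0-9]?)$")


def normalize_well_id(well: str) -> str:
    """Normalize a well id to zero-padded form (``a1`` -> ``A01``); rows run
    A-P and columns 1-24 on a 384-well plate."""
    m = _WELL_RE.match(str(well).strip())
    if not m:
        raise ValueError(f"invalid well id {well!r} for 384-well geometry (A01..P24)")
    row, col = m.group(1).upper(), int(m.group(2))
    if not 1 <= col <= 24:
        raise ValueError(f"well {well!r}: column {col} outside 1..24")
    return f"{row}{col:02d}"


def read_platemap(path: str | Path) -> pd.DataFrame:
    """Read and validate a plate-map CSV.

    Requires the header columns ``plate_id, well_id, role, compound_id,
    dose_tier, biotin``. Well ids are normalized to ``A01`` form; compound
    rows must carry a compound id and a dose tier (low/high), control rows
    must not. Errors cite 1-based data line numbers.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: plate map is missing columns {missing}")

    wells = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        where = f"{path} line {i}"
        try:
            wid = normalize_well_id(row.well_id)
        except ValueError as exc:
            raise ValueError(f"{where}: {exc}") from None
        wells.append(wid)
        if row.role not in VALID_ROLES:
            raise ValueError(f"{where}: unknown role {row.role!r}")
        if row.biotin not in ("yes", "no"):
            raise ValueError(f"{where}: biotin must be yes/no, got {row.biotin!r}")
        if row.role == "compound":
            if not row.compound_id:
                raise ValueError(f"{where}: compound row lacks compound_id")
            if row.dose_tier not in VALID_TIERS:
                raise ValueError(
                    f"{where}: compound row needs dose_tier in {sorted(VALID_TIERS)}, "
                    f"got {row.dose_tier!r}"
                )
        else:
            if row.compound_id or row.dose_tier:
                raise ValueError(f"{where}: control row must leave compound fields blank")
    df = df.assign(well_id=wells)

    dup = df.duplicated(subset=["plate_id", "well_id"])
    if dup.any():
        lines = (dup[dup].index + 1).tolist()
        keys = df.loc[dup, ["plate_id", "well_id"]].to_records(index=False).tolist()
        raise ValueError(f"{path}: duplicate wells {keys} at line(s) {lines}")
    return df[REQUIRED_COLUMNS]


def write_platemap(df: pd.DataFrame, path: str | Path) -> None:
    """Write a plate map as CSV (UTF-8, comma, header row)."""
    df[REQUIRED_COLUMNS].to_csv(path, index=False)
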