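"""Cohort table serialization: CSV canonical interchange, read-only XLSX
import through an explicit column mapping, and provenance sidecars."""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict

from . import __version__
from .cohort import BASE_COLUMNS
from .errors import SchemaError

__all__ = [
    "read_cohort_csv",
    "write_cohort_csv",
    "read_xlsx_cohort",
    "ColumnMapping",
    "write_provenance",
]

#: Columns that must be present in any cohort table.
REQUIRED_COLUMNS = ["id", "se_pre_D", "se_post_D", "vertex_mm", "r1_pre_mm", "r2_mm"]


def write_provenance(path, seed=None, config_hash=None, **extra) -> Path:
    """Write a JSON provenance sidecar next to an output file."""
    path = Path(path)
    side = path.with_suffix(path.suffix + ".provenance.json")
    side.write_text(
        json.dumps(
            {"tool": "keratrace", "version": __version__, "seed": seed,
             "config_hash": config_hash, "output": path.name, **extra},
            indent=2,
        )
    )
    return side


def write_cohort_csv(table: pd.DataFrame, path, seed=None, config_hash=None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False, float_format="%.9f")
    write_provenance(path, seed=seed, config_hash=config_hash, n=int(len(table)))
    return path


def _validate_cohort_frame(df: pd.DataFrame, source: str) -> pd.DataFrame:
    if df.empty:
        raise SchemaError(f"{source}: empty cohort")
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"{source}: missing required column {col!r}")
    known = set(BASE_COLUMNS)
    unknown = [
        c for c in df.columns
        if c not in known and not c.startswith(("pre_", "post_"))
    ]
    if unknown:
        warnings.warn(f"{source}: unknown columns preserved untouched: {unknown}")
    for col in df.columns:
        if col == "id":
            continue
        if not pd.api.types.is_numeric_dtype(df[col]):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = df[col].notna() & coerced.isna()
            if bad.any():
                line = int(bad.idxmax()) + 2  # header + 1-based
                raise SchemaError(f"{source}: non-numeric value in {col!r} near line {line}")
            warnings.warn(f"{source}: column {col!r} parsed from text")
            df[col] = coerced
    return df


def read_cohort_csv(path) -> pd.DataFrame:
    """Read a cohort CSV, enforcing the schema (dot-decimal, typed rows)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"cohort file not found: {path}")
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty cohort") from exc
    return _validate_cohort_frame(df, str(path))


class ColumnMapping(BaseModel):
    """Maps canonical cohort column names onto spreadsheet labels.

    ``columns[name] = label`` reads canonical column ``name`` from
    spreadsheet column ``label``; a value of None marks the canonical
    column as explicitly absent (imported as NaN).
    """

    model_config = ConfigDict(extra="forbid")

    sheet: str | int = 0
    columns: dict[str, str | None]


def read_xlsx_cohort(path, mapping: ColumnMapping) -> pd.DataFrame:
    """Read a cohort from a study-export-shaped workbook via a mapping."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"workbook not found: {path}")
    try:
        raw = pd.read_excel(path, sheet_name=mapping.sheet)
    except ValueError as exc:
        raise SchemaError(f"{path}: sheet {mapping.sheet!r} not readable: {exc}") from exc
    out = {}
    for canonical, label in mapping.columns.items():
        if label is None:
            out[canonical] = np.nan
            continue
        if label not in raw.columns:
            raise SchemaError(f"{path}: mapped column {label!r} (for {canonical!r}) not found")
        out[canonical] = raw[label].to_numpy()
    df = pd.DataFrame(out)
    return _validate_cohort_frame(df, str(path))
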