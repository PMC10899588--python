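"""Delimited-text readers/writers with schema validation.

All pipeline tables are plain CSV with headers.  Readers validate the column
set and value domains and point at the offending file row (1-based, counting
the header) on failure.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .dilution import SERIES_COLUMNS
from .impact import STATION_META_COLUMNS
from .risk import CELL_COLUMNS, HerbicideProps

__all__ = [
    "read_plate_table",
    "read_survey_table",
    "read_dilution_table",
    "read_cells_table",
    "read_props_table",
    "write_table",
]

PLATE_COLUMNS = ("herbicide", "concentration_nmol_L", "replicate", "response")

PROPS_COLUMNS = ("herbicide", "DT50_days", "LC50_earthworm", "LC50_fish")


class TableFormatError(ValueError):
    """A delimited-text input failed schema or value validation."""


def _read_csv(path, required: tuple[str, ...]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise TableFormatError(f"{path}: cannot parse as CSV: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing required columns {missing}")
    return df


def _check_numeric(df: pd.DataFrame, path, cols, minimum=None, strict=False) -> None:
    for col in cols:
        x = pd.to_numeric(df[col], errors="coerce")
        bad = x.index[x.isna()]
        if len(bad):
            raise TableFormatError(
                f"{path}: non-numeric value in column {col!r} at line {bad[0] + 2}")
        df[col] = x
        if minimum is not None:
            viol = x.index[x <= minimum] if strict else x.index[x < minimum]
            if len(viol):
                op = ">" if strict else ">="
                raise TableFormatError(
                    f"{path}: column {col!r} must be {op} {minimum}, "
                    f"violated at line {viol[0] + 2}")


def read_plate_table(path) -> pd.DataFrame:
    """Read a toxicity-plate table (herbicide, concentration, replicate, response)."""
    df = _read_csv(path, PLATE_COLUMNS)
    _check_numeric(df, path, ["concentration_nmol_L"], minimum=0.0)
    _check_numeric(df, path, ["response"])
    return df


def read_survey_table(path, herbicides=None) -> pd.DataFrame:
    """Read a station survey table; wide format is canonical.

    Wide: station_id, region, lat, lon, year plus one column per herbicide.
    A long table (same metadata plus herbicide, concentration columns) is
    also accepted and pivoted to wide.
    """
    df = _read_csv(path, ("station_id", "region", "year"))
    if "herbicide" in df.columns and "concentration" in df.columns:
        _check_numeric(df, path, ["concentration"], minimum=0.0)
        meta = [c for c in STATION_META_COLUMNS if c in df.columns]
        wide = df.pivot_table(index=meta, columns="herbicide",
                              values="concentration", aggfunc="sum",
                              fill_value=0.0).reset_index()
        wide.columns.name = None
        df = wide
    herb_cols = herbicides if herbicides is not None else [
        c for c in df.columns if c not in STATION_META_COLUMNS]
    _check_numeric(df, path, list(herb_cols), minimum=0.0)
    _check_numeric(df, path, ["year"])
    if "lat" in df.columns:
        _check_numeric(df, path, ["lat", "lon"])
        if (df["lat"].abs() > 90).any() or (df["lon"].abs() > 180).any():
            bad = df.index[(df["lat"].abs() > 90) | (df["lon"].abs() > 180)][0]
            raise TableFormatError(f"{path}: coordinates out of range at line {bad + 2}")
    return df


def read_dilution_table(path) -> pd.DataFrame:
    """Read a dilution-series table (size_class, dilution, replicate, P0, Pt, t_days)."""
    df = _read_csv(path, SERIES_COLUMNS)
    _check_numeric(df, path, ["dilution", "P0", "Pt", "t_days"])
    for col in ("P0", "Pt", "t_days"):
        bad = df.index[df[col] <= 0]
        if len(bad):
            raise TableFormatError(
                f"{path}: column {col!r} must be > 0, violated at line {bad[0] + 2}")
    bad = df.index[(df["dilution"] <= 0) | (df["dilution"] > 1)]
    if len(bad):
        raise TableFormatError(
            f"{path}: dilution fraction must lie in (0, 1], violated at line {bad[0] + 2}")
    return df


def read_cells_table(path) -> pd.DataFrame:
    """Read a grid-cell application table."""
    df = _read_csv(path, CELL_COLUMNS)
    _check_numeric(df, path, ["area_km2", "AR", "VDT"], minimum=0.0)
    bad = df.index[df["VDT"] > 100]
    if len(bad):
        raise TableFormatError(
            f"{path}: VDT is a percentage in [0, 100], violated at line {bad[0] + 2}")
    return df


def read_props_table(path) -> dict[str, HerbicideProps]:
    """Read a herbicide fate/toxicity properties table into a lookup."""
    df = _read_csv(path, PROPS_COLUMNS)
    _check_numeric(df, path, ["DT50_days", "LC50_earthworm", "LC50_fish"])
    out: dict[str, HerbicideProps] = {}
    for i, r in df.iterrows():
        name = str(r["herbicide"])
        if name in out:
            raise TableFormatError(
                f"{path}: duplicate herbicide {name!r} at line {i + 2}")
        dt90 = float(r["DT90_days"]) if "DT90_days" in df.columns and pd.notna(
            r.get("DT90_days")) else None
        try:
            out[name] = HerbicideProps(name, float(r["DT50_days"]),
                                       float(r["LC50_earthworm"]),
                                       float(r["LC50_fish"]), dt90)
        except ValueError as exc:
            raise TableFormatError(f"{path}: line {i + 2}: {exc}") from exc
    return out


def write_table(df: pd.DataFrame, path, float_format: str = "%.10g") -> None:
    """Write a pipeline table as CSV with stable float formatting."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=float_format)
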