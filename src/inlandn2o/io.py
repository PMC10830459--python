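"""Table readers/writers with strict schema validation, plus adapters.

All inputs are delimited text.  Gridded outputs are written as
self-describing arrays (NetCDF convention, scipy backend) with (time, cell)
dimensions; CSV ledgers carry unit-suffixed headers.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from .network import SchemaError

__all__ = [
    "REQUIRED_COLUMNS",
    "HYDROLAKES_RENAME",
    "GRAND_RENAME",
    "read_table",
    "read_tables",
    "write_tables",
    "adapt_hydrolakes",
    "adapt_grand",
    "write_gridded_emissions",
    "write_manifest",
]

REQUIRED_COLUMNS = {
    "cells": ("cell_id", "lat", "lon", "downstream_id", "country_code"),
    "reaches": ("cell_id", "corridor", "length_m", "width_m", "slope"),
    "bodies": ("body_id", "cell_id", "kind", "area_m2", "volume_m3", "depth_m",
               "residence_days", "upstream_m2", "built_year"),
    "countries": ("cell_id", "country_code"),
}

#: documented rename map from HydroLAKES attribute extracts (areas/volumes in
#: km2 / million m3 there; :func:`adapt_hydrolakes` also converts units)
HYDROLAKES_RENAME = {
    "Hylak_id": "body_id",
    "Lake_area": "area_km2",
    "Vol_total": "volume_mcm",
    "Depth_avg": "depth_m",
    "Res_time": "residence_days",
    "Wshd_area": "upstream_km2",
}

GRAND_RENAME = {
    "GRAND_ID": "body_id",
    "AREA_SKM": "area_km2",
    "CAP_MCM": "volume_mcm",
    "DEPTH_M": "depth_m",
    "RES_TIME": "residence_days",
    "CATCH_SKM": "upstream_km2",
    "YEAR": "built_year",
}


def read_table(path, table: str) -> pd.DataFrame:
    """Read one CSV and check its columns against the schema contract."""
    if table not in REQUIRED_COLUMNS:
        raise ValueError(f"unknown table type {table!r}")
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS[table] if c not in df.columns]
    if missing:
        raise SchemaError(f"{table} table {path}: missing required column(s) {missing}")
    return df


def read_tables(directory):
    """Read cells/reaches/bodies/countries from a directory."""
    from .synthetic_data import NetworkTables

    d = Path(directory)
    return NetworkTables(
        cells=read_table(d / "cells.csv", "cells"),
        reaches=read_table(d / "reaches.csv", "reaches"),
        bodies=read_table(d / "bodies.csv", "bodies"),
        countries=read_table(d / "countries.csv", "countries"),
    )


def write_tables(directory, tables) -> None:
    tables.write(directory)


def _adapt(df: pd.DataFrame, rename: dict[str, str], kind: str,
           cell_id: int | pd.Series) -> pd.DataFrame:
    missing = [c for c in rename if c not in df.columns]
    if missing:
        raise SchemaError(f"extract is missing expected column(s) {missing}")
    out = df.rename(columns=rename)[list(rename.values())].copy()
    out["area_m2"] = out.pop("area_km2") * 1e6
    out["volume_m3"] = out.pop("volume_mcm") * 1e6
    out["upstream_m2"] = out.pop("upstream_km2") * 1e6
    out["kind"] = kind
    out["cell_id"] = cell_id
    if kind == "lake":
        out["built_year"] = None
    return out[list(REQUIRED_COLUMNS["bodies"])]


def adapt_hydrolakes(df: pd.DataFrame, cell_id: int | pd.Series = 0) -> pd.DataFrame:
    """Turn a HydroLAKES-style attribute extract into the bodies.csv schema."""
    return _adapt(df, HYDROLAKES_RENAME, "lake", cell_id)


def adapt_grand(df: pd.DataFrame, cell_id: int | pd.Series = 0) -> pd.DataFrame:
    """Turn a GRanD-style attribute extract into the bodies.csv schema."""
    return _adapt(df, GRAND_RENAME, "reservoir", cell_id)


DAILY_FORCING_COLUMNS = ("cell_id", "day", "runoff_m3_d", "no3_gN_d",
                         "nh4_gN_d", "don_gN_d", "pon_gN_d")


def write_daily_forcing(path, cell_ids, runoff, loads) -> None:
    """Write per-cell daily runoff + species loads as a tidy CSV.

    ``runoff`` has shape (n_days, n_cells); ``loads`` (n_days, n_cells, 4)
    in species order no3, nh4, don, pon.
    """
    runoff = np.asarray(runoff)
    loads = np.asarray(loads)
    n_days, n_cells = runoff.shape
    df = pd.DataFrame({
        "cell_id": np.tile(np.asarray(cell_ids), n_days),
        "day": np.repeat(np.arange(n_days), n_cells),
        "runoff_m3_d": runoff.ravel(),
        "no3_gN_d": loads[:, :, 0].ravel(),
        "nh4_gN_d": loads[:, :, 1].ravel(),
        "don_gN_d": loads[:, :, 2].ravel(),
        "pon_gN_d": loads[:, :, 3].ravel(),
    })
    df.to_csv(path, index=False)


def read_daily_forcing(path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Read a daily-forcing CSV back into (cell_ids, runoff, loads) arrays."""
    df = pd.read_csv(path)
    missing = [c for c in DAILY_FORCING_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"daily forcing table {path}: missing column(s) {missing}")
    df = df.sort_values(["day", "cell_id"], kind="stable")
    cell_ids = np.sort(df.cell_id.unique())
    n_days = df.day.nunique()
    n_cells = cell_ids.size
    runoff = df.runoff_m3_d.to_numpy().reshape(n_days, n_cells)
    loads = np.stack([df[c].to_numpy().reshape(n_days, n_cells)
                      for c in ("no3_gN_d", "nh4_gN_d", "don_gN_d", "pon_gN_d")],
                     axis=2)
    return cell_ids, runoff, loads


def write_gridded_emissions(path, years, cell_ids, emissions_g_n) -> None:
    """Write an annual (time, cell) emission array as a NetCDF file."""
    ds = xr.Dataset(
        {"n2o_efflux": (("time", "cell"), np.asarray(emissions_g_n, dtype=float))},
        coords={"time": np.asarray(years), "cell": np.asarray(cell_ids)},
    )
    ds.n2o_efflux.attrs["units"] = "g N yr-1"
    ds.attrs["convention"] = "time: calendar years; cell: network cell ids"
    ds.to_netcdf(path, engine="scipy")


def write_manifest(path, manifest: dict) -> None:
    import yaml

    with open(path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
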