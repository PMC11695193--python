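"""File-format round-trips for scene and pipeline artifacts.

Raster stacks and county maps travel as NetCDF (written through xarray's
scipy backend, so no compiled NetCDF library is required); tables travel
as plain CSV.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from .containers import CountyMap, CountySeries, GridStack

__all__ = [
    "write_gridstack",
    "read_gridstack",
    "write_county_map",
    "read_county_map",
    "write_yield_table",
    "read_yield_table",
    "write_county_series",
    "read_county_series",
]


def write_gridstack(stack: GridStack, path: str | Path) -> None:
    """Write a stack as NetCDF with a day-of-season time coordinate."""
    ds = xr.Dataset(
        {stack.variable: (("time", "row", "col"), stack.values)},
        coords={"time": stack.start_dates},
        attrs={"nodata": float(stack.nodata), "variable": stack.variable},
    )
    ds.to_netcdf(path, engine="scipy")


def read_gridstack(path: str | Path) -> GridStack:
    with xr.open_dataset(path, engine="scipy") as ds:
        name = ds.attrs["variable"]
        return GridStack(
            name,
            ds[name].values.astype(float),
            ds["time"].values.astype(int),
            nodata=float(ds.attrs.get("nodata", np.nan)),
        )


def write_county_map(county_map: CountyMap, path: str | Path) -> None:
    ds = xr.Dataset(
        {
            "county_id": (("row", "col"), county_map.county_ids.astype("int32")),
            "cropland": (("row", "col"), county_map.cropland.astype("int8")),
        }
    )
    ds.to_netcdf(path, engine="scipy")


def read_county_map(path: str | Path) -> CountyMap:
    with xr.open_dataset(path, engine="scipy") as ds:
        return CountyMap(ds["county_id"].values, ds["cropland"].values.astype(bool))


def write_yield_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def read_yield_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_county_series(series: list[CountySeries], path: str | Path) -> None:
    """Long-format CSV: county_id, year, composite_index, feature, value."""
    frames = []
    for s in series:
        T, F = s.values.shape
        frames.append(
            pd.DataFrame(
                {
                    "county_id": np.repeat(s.county_id, T * F),
                    "year": np.repeat(s.year, T * F),
                    "composite_index": np.tile(np.repeat(np.arange(T), F), 1),
                    "feature": np.tile(list(s.feature_names), T),
                    "value": s.values.ravel(),
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_county_series(path: str | Path, composite_dates=None) -> list[CountySeries]:
    df = pd.read_csv(path)
    out = []
    for (cid, year), grp in df.groupby(["county_id", "year"], sort=True):
        piv = grp.pivot(index="composite_index", columns="feature", values="value")
        features = tuple(dict.fromkeys(grp["feature"]))  # original order
        piv = piv[list(features)]
        dates = (
            np.asarray(composite_dates)
            if composite_dates is not None
            else piv.index.to_numpy() * 8
        )
        out.append(CountySeries(int(cid), int(year), piv.to_numpy(), features, dates))
    return out
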