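"""NetCDF serialization for fields and masks (CF-style, NETCDF3 classic).

Fields are written with dimensions (time, lat, lon), the variable ``tas``
in degC, coordinates at cell centers, and the monthly axis encoded as an
integer index with ``start_year``/``start_month`` attributes.  An adapter
entry point :func:`read_monthly_field` also accepts externally supplied
files whose temperature variable is named differently or is in kelvin.
"""
from __future__ import annotations

from typing import Optional

import numpy as np
import xarray as xr

from .errors import InputError
from .grid import LandMask, MonthTime, MonthlyField, RegularGrid

_ENGINE = "scipy"  # NETCDF3_CLASSIC; no external netCDF4 dependency


def _grid_from_coords(lat: np.ndarray, lon: np.ndarray) -> RegularGrid:
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    if lat.size < 2 or lon.size < 2:
        raise InputError("need at least 2 coordinates per axis to infer a grid")
    dlat = float(np.mean(np.diff(lat)))
    dlon = float(np.mean(np.diff(lon)))
    if dlat <= 0:
        raise InputError("latitude coordinates must be ascending")
    return RegularGrid(
        lat_edge_south=float(lat[0]) - dlat / 2.0,
        lon_edge_west=float(lon[0]) - dlon / 2.0,
        lat_step=dlat,
        lon_step=dlon,
        n_lat=lat.size,
        n_lon=lon.size,
    )


def field_to_dataset(field: MonthlyField, method_note: str = "") -> xr.Dataset:
    ds = xr.Dataset(
        {
            "tas": (
                ("time", "lat", "lon"),
                field.values,
                {"units": "degC", "long_name": "near-surface air temperature"},
            )
        },
        coords={
            "time": ("time", np.arange(field.time.n_months, dtype=np.int32)),
            "lat": ("lat", field.grid.lat_centers, {"units": "degrees_north"}),
            "lon": ("lon", field.grid.lon_centers, {"units": "degrees_east"}),
        },
        attrs={
            "start_year": field.time.start_year,
            "start_month": field.time.start_month,
            "calendar": "uniform-12-month",
        },
    )
    if method_note:
        ds.attrs["history"] = method_note
    if field.missing_mask is not None:
        ds["missing_mask"] = (
            ("lat", "lon"),
            field.missing_mask.astype(np.int8),
            {"long_name": "1 where the cell carries no data"},
        )
    return ds


def write_monthly_field(field: MonthlyField, path, method_note: str = "") -> None:
    field_to_dataset(field, method_note).to_netcdf(path, engine=_ENGINE)


def dataset_to_field(ds: xr.Dataset, var: Optional[str] = None) -> MonthlyField:
    if var is None:
        candidates = [v for v in ("tas", "tmp", "temperature") if v in ds]
        if not candidates:
            candidates = [v for v in ds.data_vars if ds[v].ndim == 3]
        if not candidates:
            raise InputError("no 3-D temperature variable found")
        var = candidates[0]
    da = ds[var]
    values = np.asarray(da.values, dtype=float)
    units = str(da.attrs.get("units", "degC")).lower()
    if units in ("k", "kelvin"):
        values = values - 273.15
    grid = _grid_from_coords(ds["lat"].values, ds["lon"].values)
    start_year = int(ds.attrs.get("start_year", 1901))
    start_month = int(ds.attrs.get("start_month", 1))
    time = MonthTime(start_year, start_month, values.shape[0])
    missing = None
    if "missing_mask" in ds:
        missing = np.asarray(ds["missing_mask"].values).astype(bool)
    elif np.isnan(values).any():
        missing = np.isnan(values).all(axis=0)
    return MonthlyField(grid, time, values, missing)


def read_monthly_field(path, var: Optional[str] = None) -> MonthlyField:
    with xr.open_dataset(path, engine=_ENGINE, decode_times=False) as ds:
        return dataset_to_field(ds.load(), var=var)


def write_land_mask(mask: LandMask, path) -> None:
    ds = xr.Dataset(
        {"land_mask": (("lat", "lon"), mask.is_land.astype(np.int8))},
        coords={
            "lat": ("lat", mask.grid.lat_centers, {"units": "degrees_north"}),
            "lon": ("lon", mask.grid.lon_centers, {"units": "degrees_east"}),
        },
    )
    ds.to_netcdf(path, engine=_ENGINE)


def read_land_mask(path) -> LandMask:
    with xr.open_dataset(path, engine=_ENGINE, decode_times=False) as ds:
        grid = _grid_from_coords(ds["lat"].values, ds["lon"].values)
        return LandMask(grid, np.asarray(ds["land_mask"].values).astype(bool))
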