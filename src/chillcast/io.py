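"""NetCDF I/O for daily field and ensemble cubes.

Cubes are stored CF-style: dimensions (time, lat, lon[, member]), a ``units``
attribute on the variable, and the time axis encoded as days since a
reference date.  Files are written in NetCDF3 classic format (via scipy),
which every NetCDF reader understands.  On read, axes are validated
(monotone, daily time step), latitudes are returned ascending and longitudes
normalized to [0, 360).
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd
import xarray as xr

from ._calendar import require_daily

__all__ = ["read_cube", "write_cube"]

_ENGINE = "scipy"


def write_cube(cube: xr.DataArray, path, name: Optional[str] = None) -> None:
    """Write a (time, lat, lon[, member]) cube as CF-style NetCDF."""
    var = name or cube.name or "data"
    ds = cube.to_dataset(name=var)
    encoding = {}
    if "time" in ds.coords:
        t0 = pd.Timestamp(np.asarray(ds["time"].values).min())
        encoding["time"] = {"units": f"days since {t0:%Y-%m-%d}", "dtype": "int32"}
    for coord in ("init_date",):
        if coord in ds.coords:
            # NetCDF3 cannot hold a second datetime coordinate cleanly; store ISO
            ds = ds.assign_coords(
                {coord: ds[coord].dt.strftime("%Y-%m-%d").astype("S10")}
            )
    ds.to_netcdf(path, engine=_ENGINE, encoding=encoding)


def read_cube(path, expected_units: Optional[str] = None, var: Optional[str] = None) -> xr.DataArray:
    """Read a cube written by :func:`write_cube` (or any CF NetCDF alike).

    Validates the units attribute against ``expected_units`` when given,
    checks for a gap-free daily time axis, sorts latitudes ascending and
    maps longitudes into [0, 360).
    """
    ds = xr.open_dataset(path, engine=_ENGINE)
    data_vars = list(ds.data_vars)
    if var is None:
        if len(data_vars) != 1:
            raise ValueError(f"file holds {data_vars}; pass var= to pick one")
        var = data_vars[0]
    cube = ds[var].load()
    ds.close()
    units = cube.attrs.get("units")
    if units is None:
        raise ValueError(f"variable {var!r} has no units attribute")
    if expected_units is not None and units != expected_units:
        raise ValueError(f"variable {var!r} has units {units!r}, expected {expected_units!r}")
    if "time" in cube.dims:
        require_daily(cube["time"].values, f"{var} time axis")
    if "lat" in cube.dims:
        lat = cube["lat"].values
        if lat.size > 1 and lat[0] > lat[-1]:
            cube = cube.isel(lat=slice(None, None, -1))
        if not np.all(np.diff(cube["lat"].values) > 0):
            raise ValueError("latitude axis is not monotone")
    if "lon" in cube.dims:
        lon = np.mod(cube["lon"].values, 360.0)
        cube = cube.assign_coords(lon=lon).sortby("lon")
        if not np.all(np.diff(cube["lon"].values) > 0):
            raise ValueError("longitude axis is not monotone after normalization")
    if "init_date" in cube.coords and cube["init_date"].dtype.kind == "S":
        cube = cube.assign_coords(
            init_date=(
                cube["init_date"].dims,
                pd.to_datetime(
                    [b.decode() for b in np.atleast_1d(cube["init_date"].values)]
                ).values,
            )
        )
    return cube
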