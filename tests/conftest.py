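import numpy as np
import pandas as pd
import pytest
import xarray as xr

from chillcast.synthetic import (
    BackgroundConfig,
    EventConfig,
    GridConfig,
    SyntheticConfig,
)


@pytest.fixture(scope="session")
def small_grid() -> GridConfig:
    """5x5 one-degree grid with the event center exactly on a grid point."""
    return GridConfig(
        n_lat=5, n_lon=5, lat_min=-22.5, lat_max=-18.5, lon_min=139.0, lon_max=143.0
    )


@pytest.fixture(scope="session")
def small_config(small_grid) -> SyntheticConfig:
    return SyntheticConfig(
        grid=small_grid, start="2016-01-01", end="2019-12-31", seed=7
    )


def make_cube(values, times=None, lat=None, lon=None, units="mm/day", name="x"):
    values = np.asarray(values, dtype=float)
    if times is None:
        times = pd.date_range("2019-01-01", periods=values.shape[0], freq="D")
    if lat is None:
        lat = np.arange(values.shape[1], dtype=float) - 20.0
    if lon is None:
        lon = np.arange(values.shape[2], dtype=float) + 140.0
    return xr.DataArray(
        values,
        dims=("time", "lat", "lon"),
        coords={"time": times, "lat": lat, "lon": lon},
        name=name,
        attrs={"units": units},
    )
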