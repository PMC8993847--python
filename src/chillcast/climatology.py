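"""Multi-year calendar-day percentile climatologies and exceedance diagnostics.

Extremes are defined relative to the annual cycle: for each calendar day and
grid point, all values falling within a centered window (default 15 days) of
that day — pooled across every year and, for hindcasts, every ensemble
member — form the sample from which an empirical percentile threshold is
taken.  A day is "extreme" when its value strictly exceeds (or, for cold
extremes, falls strictly below) its calendar-day threshold.  Run-length and
area-aggregation utilities summarise the resulting exceedance masks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd
import xarray as xr

from ._calendar import DAYS_PER_YEAR, doy365, require_daily, window_days

__all__ = [
    "CalendarClimatology",
    "RegionBox",
    "EventSummary",
    "GULF_REGION",
    "calendar_percentile",
    "exceedance_mask",
    "longest_run",
    "area_average",
    "area_fraction_exceeding",
]


@dataclass(frozen=True)
class RegionBox:
    """A lat/lon rectangle; south latitudes are negative."""

    lon_min: float = 137.0
    lon_max: float = 145.0
    lat_min: float = -23.0
    lat_max: float = -18.0

    def __post_init__(self) -> None:
        if not self.lon_min < self.lon_max:
            raise ValueError("lon_min must be < lon_max")
        if not self.lat_min < self.lat_max:
            raise ValueError("lat_min must be < lat_max")


#: The inland Gulf of Carpentaria box (137-145 E, 18-23 S) over which the
#: area-averaged chill series and exceedance fractions are computed.
GULF_REGION = RegionBox()


@dataclass
class EventSummary:
    """Onset/offset/duration of the longest consecutive exceedance run."""

    onset: Optional[pd.Timestamp] = None
    offset: Optional[pd.Timestamp] = None
    duration: int = 0
    peak_value: Optional[float] = None
    peak_date: Optional[pd.Timestamp] = None


@dataclass
class CalendarClimatology:
    """Per-grid-point, per-calendar-day percentile thresholds.

    ``thresholds`` has dims (dayofyear, lat, lon) with dayofyear in 1..365
    (Feb 29 shares day 59 with Feb 28).  ``n_pool`` records, per calendar
    day, how many member-days entered the pooled sample; for a full record
    this is window_days x n_years x n_members away from the leap-day fold.
    """

    thresholds: xr.DataArray
    q: float
    window_days: int
    n_pool: np.ndarray
    n_years: int
    n_members: int
    source_period: str = ""
    provenance: dict = field(default_factory=dict)

    def threshold_for_dates(self, times) -> xr.DataArray:
        """Thresholds aligned to a concrete daily time axis."""
        doy = doy365(times)
        thr = self.thresholds.isel(dayofyear=xr.DataArray(doy - 1, dims="time"))
        return thr.assign_coords(time=("time", pd.DatetimeIndex(times)))

    def to_dataset(self) -> xr.Dataset:
        ds = self.thresholds.to_dataset(name="threshold")
        ds["n_pool"] = ("dayofyear", self.n_pool)
        ds.attrs.update(
            q=self.q,
            window_days=self.window_days,
            n_years=self.n_years,
            n_members=self.n_members,
            source_period=self.source_period,
        )
        return ds

    @classmethod
    def from_dataset(cls, ds: xr.Dataset) -> "CalendarClimatology":
        return cls(
            thresholds=ds["threshold"],
            q=float(ds.attrs["q"]),
            window_days=int(ds.attrs["window_days"]),
            n_pool=np.asarray(ds["n_pool"].values, dtype=int),
            n_years=int(ds.attrs["n_years"]),
            n_members=int(ds.attrs["n_members"]),
            source_period=str(ds.attrs.get("source_period", "")),
        )


def _pool_arrays(cubes: Iterable[xr.DataArray]):
    """Flatten (member x time) into one pooled obs axis with a doy per row."""
    blocks, doys, years, n_members = [], [], set(), None
    for cube in cubes:
        da = cube
        if "member" not in da.dims:
            da = da.expand_dims(member=[0])
        nm = da.sizes["member"]
        if n_members is None:
            n_members = nm
        elif n_members != nm:
            raise ValueError("member axes are inconsistent across inputs")
        da = da.transpose("member", "time", "lat", "lon")
        times = pd.DatetimeIndex(da["time"].values)
        years.update(times.year.unique())
        d = doy365(times)
        vals = da.values.reshape(nm * da.sizes["time"], da.sizes["lat"], da.sizes["lon"])
        blocks.append(vals)
        doys.append(np.tile(d, nm))
    return np.concatenate(blocks, axis=0), np.concatenate(doys), len(years), n_members


def calendar_percentile(
    data,
    q: float,
    window: int = 15,
) -> CalendarClimatology:
    """Empirical calendar-day q-quantile thresholds from a multi-year record.

    Parameters
    ----------
    data : a daily (time, lat, lon) cube, an ensemble (member, time, lat,
        lon) cube, or a list of such cubes (e.g. one hindcast per year);
        members are pooled into the sample before the quantile is taken.
    q : quantile level in (0, 1), e.g. 0.9 for the 90th percentile.
    window : odd centered-window width in days pooling neighbouring calendar
        days; the window wraps across the Dec-Jan boundary.

    The empirical quantile uses linear interpolation between closest order
    statistics (numpy's default), applied to the pooled member-day sample of
    each calendar day and grid cell.  Missing values are excluded cell-wise.
    """
    if not 0.0 < q < 1.0:
        raise ValueError("q must be in (0, 1)")
    if window % 2 == 0 or window < 1:
        raise ValueError("window must be odd and >= 1")
    cubes = list(data) if isinstance(data, (list, tuple)) else [data]
    if not cubes:
        raise ValueError("no input data")
    pooled, doys, n_years, n_members = _pool_arrays(cubes)
    if n_years < 2:
        raise ValueError(f"need at least 2 distinct years, got {n_years}")

    lat = cubes[0]["lat"].values
    lon = cubes[0]["lon"].values
    thr = np.empty((DAYS_PER_YEAR, lat.size, lon.size))
    n_pool = np.empty(DAYS_PER_YEAR, dtype=int)
    for day in range(1, DAYS_PER_YEAR + 1):
        sel = np.isin(doys, window_days(day, window))
        sample = pooled[sel]
        n_pool[day - 1] = sample.shape[0]
        if sample.shape[0] == 0:
            thr[day - 1] = np.nan
        else:
            thr[day - 1] = np.nanquantile(sample, q, axis=0)

    times = np.concatenate([np.asarray(c["time"].values) for c in cubes])
    period = f"{pd.Timestamp(times.min()):%Y-%m-%d}..{pd.Timestamp(times.max()):%Y-%m-%d}"
    thresholds = xr.DataArray(
        thr,
        dims=("dayofyear", "lat", "lon"),
        coords={"dayofyear": np.arange(1, DAYS_PER_YEAR + 1), "lat": lat, "lon": lon},
        name="threshold",
        attrs={"units": cubes[0].attrs.get("units", "")},
    )
    return CalendarClimatology(
        thresholds=thresholds,
        q=q,
        window_days=window,
        n_pool=n_pool,
        n_years=n_years,
        n_members=n_members,
        source_period=period,
    )


def exceedance_mask(
    cube: xr.DataArray,
    clim: CalendarClimatology,
    direction: str = "above",
) -> xr.DataArray:
    """Boolean cube marking strict exceedance of the calendar-day threshold.

    ``direction="above"`` flags value > threshold, ``"below"`` flags
    value < threshold; ties never count.  Missing values map to False and
    are recorded in a companion ``missing`` coordinate.
    """
    if direction not in ("above", "below"):
        raise ValueError("direction must be 'above' or 'below'")
    thr = clim.threshold_for_dates(cube["time"].values)
    thr = thr.transpose(*[d for d in cube.dims if d in thr.dims])
    if "member" in cube.dims:
        thr = thr.broadcast_like(cube)
    mask = cube > thr if direction == "above" else cube < thr
    missing = cube.isnull()
    mask = mask.where(~missing, False).astype(bool)
    mask = mask.assign_coords(missing=missing)
    mask.attrs = {
        "direction": direction,
        "q": clim.q,
        "window_days": clim.window_days,
    }
    return mask


def longest_run(mask, values=None) -> EventSummary:
    """Longest run of consecutive True days in a daily boolean series.

    Returns the first maximal run on ties.  With ``values`` supplied on the
    same axis, the run's peak value and peak date are reported too.  An
    all-False mask yields duration 0 with null dates.
    """
    if isinstance(mask, xr.DataArray):
        times = mask["time"].values
        flags = np.asarray(mask.values, dtype=bool)
    else:
        series = pd.Series(mask)
        times = series.index
        flags = series.to_numpy(dtype=bool)
    idx = require_daily(times, "mask series")
    best_len, best_start, run_len = 0, 0, 0
    for i, f in enumerate(flags):
        run_len = run_len + 1 if f else 0
        if run_len > best_len:
            best_len = run_len
            best_start = i - run_len + 1
    if best_len == 0:
        return EventSummary()
    onset, offset = idx[best_start], idx[best_start + best_len - 1]
    summary = EventSummary(onset=onset, offset=offset, duration=best_len)
    if values is not None:
        vals = np.asarray(
            values.values if isinstance(values, xr.DataArray) else values, dtype=float
        )
        window = vals[best_start : best_start + best_len]
        peak = int(np.nanargmax(window))
        summary.peak_value = float(window[peak])
        summary.peak_date = idx[best_start + peak]
    return summary


def _region_weights(cube: xr.DataArray, region: RegionBox) -> xr.DataArray:
    sel = cube.sel(
        lat=slice(region.lat_min, region.lat_max),
        lon=slice(region.lon_min, region.lon_max),
    )
    if sel.sizes.get("lat", 0) == 0 or sel.sizes.get("lon", 0) == 0:
        raise ValueError("region selects no grid cells")
    weights = np.cos(np.deg2rad(sel["lat"]))
    return sel, weights


def area_average(cube: xr.DataArray, region: RegionBox = GULF_REGION) -> xr.DataArray:
    """Cosine-latitude-weighted mean over the box; missing cells drop out."""
    sel, weights = _region_weights(cube, region)
    out = sel.weighted(weights).mean(dim=("lat", "lon"), skipna=True)
    out.attrs = dict(cube.attrs)
    return out


def area_fraction_exceeding(
    mask: xr.DataArray, region: RegionBox = GULF_REGION
) -> xr.DataArray:
    """Cosine-latitude-weighted fraction of box cells that are True."""
    sel, weights = _region_weights(mask, region)
    return sel.astype(float).weighted(weights).mean(dim=("lat", "lon"))
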