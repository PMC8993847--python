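"""Lagged-ensemble assembly, quantile-matching calibration, probability maps.

Multi-week forecasts are often built as lagged ensembles: members from several
consecutive initialization dates are pooled, trimmed to the common valid-time
range, into one larger ensemble (e.g. 33 members/day over 3 days = 99).  Raw
model output can be calibrated against an observed record by empirical
quantile-quantile matching, mapping each value through the model CDF and the
inverse observed CDF per grid cell.  The probability of an extreme week is
the fraction of members whose week-averaged value strictly exceeds the
week-averaged calendar-day percentile threshold (a per-day counting mode is
also available).
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import xarray as xr

from ._calendar import doy365, window_days
from .climatology import CalendarClimatology

__all__ = [
    "assemble_lagged_ensemble",
    "quantile_map_calibrate",
    "prob_extreme",
    "match_hindcast_init",
]


def assemble_lagged_ensemble(runs: Sequence[xr.DataArray]) -> xr.DataArray:
    """Pool members from several initialization dates into one ensemble.

    All runs must share the lat/lon grid and have distinct init dates; the
    result is trimmed to the intersection of valid times, concatenating the
    member axes (total members = sum over runs).  Each member keeps its own
    ``init_date`` coordinate.
    """
    runs = list(runs)
    if not runs:
        raise ValueError("no runs supplied")
    if len(runs) == 1:
        return runs[0]
    first = runs[0]
    inits = []
    for run in runs:
        if "init_date" not in run.coords:
            raise ValueError("each run needs an init_date coordinate on member")
        inits.append(pd.Timestamp(np.asarray(run["init_date"].values).min()))
        for dim in ("lat", "lon"):
            if not np.array_equal(run[dim].values, first[dim].values):
                raise ValueError("runs are on different grids")
    if len(set(inits)) != len(inits):
        raise ValueError("init dates must be distinct")
    t0 = max(pd.Timestamp(np.asarray(r["time"].values).min()) for r in runs)
    t1 = min(pd.Timestamp(np.asarray(r["time"].values).max()) for r in runs)
    if t0 > t1:
        raise ValueError("runs have no overlapping valid times")
    trimmed = [r.sel(time=slice(t0, t1)) for r in runs]
    out = xr.concat(trimmed, dim="member")
    out = out.assign_coords(member=np.arange(out.sizes["member"]))
    out.attrs = dict(first.attrs)
    out.attrs["n_init_dates"] = len(runs)
    return out


def _ecdf_positions(n: int) -> np.ndarray:
    # positions of the linear-interpolation quantile rule (h = (n-1) q), the
    # same convention the climatology thresholds use; the round trip through
    # one pool is then the exact identity for in-pool values
    if n == 1:
        return np.array([0.5])
    return np.arange(n) / (n - 1)


def _qq_map_1d(x: np.ndarray, model_pool: np.ndarray, obs_pool: np.ndarray) -> np.ndarray:
    m = np.sort(model_pool[np.isfinite(model_pool)])
    o = np.sort(obs_pool[np.isfinite(obs_pool)])
    if m.size == 0 or o.size == 0:
        raise ValueError("empty calibration pool")
    p = np.interp(x, m, _ecdf_positions(m.size))
    return np.interp(p, _ecdf_positions(o.size), o)


def quantile_map_calibrate(
    model_hindcast: xr.DataArray,
    obs_data: xr.DataArray,
    forecast: xr.DataArray,
    window: Optional[int] = None,
) -> xr.DataArray:
    """Empirical quantile-quantile calibration of a forecast, per grid cell.

    Each forecast value x is mapped through F_obs^{-1}(F_model(x)), where the
    empirical CDFs come from the pooled model hindcast (members x times) and
    the observed record.  The map is monotone, so member ranking at a cell
    is preserved, and calibrating a pool onto itself is the identity for
    in-pool values.  With ``window`` set (odd, days), the pools for each
    forecast day are restricted to a centered calendar-day window, making
    the correction seasonally varying.
    """
    for dim in ("lat", "lon"):
        if not np.array_equal(forecast[dim].values, model_hindcast[dim].values):
            raise ValueError("hindcast and forecast are on different grids")
        if not np.array_equal(forecast[dim].values, obs_data[dim].values):
            raise ValueError("observations and forecast are on different grids")
    hind = model_hindcast
    if "member" in hind.dims:
        hind = hind.stack(obs=("member", "time")).transpose("obs", "lat", "lon")
    else:
        hind = hind.rename({"time": "obs"}).transpose("obs", "lat", "lon")
    obs = obs_data.transpose("time", "lat", "lon")

    fc = forecast.transpose("member", "time", "lat", "lon")
    out = np.empty(fc.shape)
    nlat, nlon = fc.sizes["lat"], fc.sizes["lon"]
    hind_vals = hind.values
    obs_vals = obs.values
    fc_vals = fc.values

    if window is None:
        for i in range(nlat):
            for j in range(nlon):
                out[:, :, i, j] = _qq_map_1d(
                    fc_vals[:, :, i, j].ravel(), hind_vals[:, i, j], obs_vals[:, i, j]
                ).reshape(fc_vals.shape[:2])
    else:
        if window % 2 == 0 or window < 1:
            raise ValueError("window must be odd and >= 1")
        hind_doy = doy365(model_hindcast["time"].values)
        if "member" in model_hindcast.dims:
            hind_doy = np.tile(hind_doy, model_hindcast.sizes["member"])
        obs_doy = doy365(obs_data["time"].values)
        fc_doy = doy365(fc["time"].values)
        for t, day in enumerate(fc_doy):
            days = window_days(int(day), window)
            hsel = np.isin(hind_doy, days)
            osel = np.isin(obs_doy, days)
            for i in range(nlat):
                for j in range(nlon):
                    out[:, t, i, j] = _qq_map_1d(
                        fc_vals[:, t, i, j], hind_vals[hsel, i, j], obs_vals[osel, i, j]
                    )
    result = xr.DataArray(out, coords=fc.coords, dims=fc.dims, name=forecast.name)
    result.attrs = dict(forecast.attrs)
    result.attrs["calibration"] = "empirical quantile-quantile vs observations"
    return result


def prob_extreme(
    forecast: xr.DataArray,
    clim: CalendarClimatology,
    window: Tuple,
    mode: str = "weekly_mean",
) -> xr.DataArray:
    """Per-grid-point probability of extreme conditions in a target window.

    ``window`` is an inclusive (start, end) date pair (the headline analysis
    uses a 7-day target week).  Default mode ``weekly_mean``: each member's
    window-mean value is compared (strictly) with the window-mean of the
    daily thresholds, and p = exceeding members / n_members.  Mode
    ``daily_count``: p is the mean daily member-exceedance fraction.  The
    mode and threshold provenance are recorded in the output attributes.
    """
    start, end = pd.Timestamp(window[0]), pd.Timestamp(window[1])
    if start > end:
        raise ValueError("window start must be <= end")
    fc = forecast.sel(time=slice(start, end))
    n_days = (end - start).days + 1
    if fc.sizes.get("time", 0) != n_days:
        raise ValueError("forecast does not cover the target window")
    thr = clim.threshold_for_dates(fc["time"].values)
    if mode == "weekly_mean":
        exceed = fc.mean("time") > thr.mean("time")
        p = exceed.mean("member")
    elif mode == "daily_count":
        exceed = fc > thr
        p = exceed.mean(("member", "time"))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    p = p.astype(float)
    p.name = "prob_extreme"
    p.attrs = {
        "mode": mode,
        "n_members": int(forecast.sizes["member"]),
        "q": clim.q,
        "threshold_window_days": clim.window_days,
        "threshold_source_period": clim.source_period,
        "target_window": f"{start:%Y-%m-%d}..{end:%Y-%m-%d}",
    }
    return p


def match_hindcast_init(forecast_init, available_hindcast_inits) -> pd.Timestamp:
    """Nearest hindcast initialization date to a forecast init (ties: earlier).

    Real-time forecasts are verified against percentile thresholds from the
    hindcast start date closest in the calendar, with exact matches
    preferred.
    """
    candidates = [pd.Timestamp(d) for d in available_hindcast_inits]
    if not candidates:
        raise ValueError("no hindcast init dates available")
    target = pd.Timestamp(forecast_init)
    return min(candidates, key=lambda d: (abs((d - target).days), d))
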