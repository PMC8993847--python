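"""MJO phase-space diagnostics: amplitude/phase, stall residence, composites.

The Madden-Julian Oscillation is tracked by the bivariate (RMM1, RMM2) index.
Amplitude is sqrt(RMM1^2 + RMM2^2); the MJO is "active" when the amplitude is
at least 1 (outside the unit circle of the phase diagram).  Phase is the
octant of atan2(RMM2, RMM1) under the standard Wheeler-Hendon layout
(counterclockwise, half-open boundaries):

    angle [180, 225) -> 1   [225, 270) -> 2   [270, 315) -> 3   [315, 360) -> 4
    angle [0, 45)    -> 5   [45, 90)   -> 6   [90, 135)  -> 7   [135, 180) -> 8

A "stall" is an active MJO remaining within a phase subset (here the western
Pacific, phases 6-7) for an unusually long residence time; alternation within
the subset (6 <-> 7) does not break a run.  Ensemble members are split into
stalled / fast subsets by their residence, and weighted multi-model MSLP
anomaly composites are built for each subset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import xarray as xr

from ._calendar import DAYS_PER_YEAR, doy365, require_daily

__all__ = [
    "StallCriteria",
    "CompositeConfig",
    "amplitude_phase",
    "rmm_series",
    "read_rmm",
    "write_rmm",
    "residence_time",
    "classify_members",
    "anomaly_vs_smoothed_clim",
    "weighted_composite",
]

#: amplitude at or above which the MJO counts as active
ACTIVE_AMPLITUDE = 1.0


@dataclass(frozen=True)
class StallCriteria:
    """Thresholds splitting members into stalled vs fast MJO passages.

    Members whose residence in ``phase_set`` is >= ``stall_min_days`` are
    "stalled"; residence < ``fast_max_days`` is "fast"; the band in between
    belongs to neither subset.  ``require_active`` demands amplitude >= 1 on
    every counted day; ``max_gap_days`` allows short interruptions without
    breaking a run (0 = strict contiguity).
    """

    phase_set: frozenset = frozenset({6, 7})
    stall_min_days: int = 17
    fast_max_days: int = 13
    require_active: bool = True
    max_gap_days: int = 0

    def __post_init__(self) -> None:
        if not self.fast_max_days < self.stall_min_days:
            raise ValueError("fast_max_days must be < stall_min_days")
        if not set(self.phase_set) <= set(range(1, 9)):
            raise ValueError("phase_set must be a subset of {1..8}")


@dataclass(frozen=True)
class CompositeConfig:
    """Settings for the subset MSLP composites."""

    clim_smoothing_days: int = 11
    window_start: str = "2019-02-02"
    window_end: str = "2019-02-06"

    def __post_init__(self) -> None:
        if self.clim_smoothing_days % 2 == 0:
            raise ValueError("smoothing window must be odd")


def amplitude_phase(rmm1, rmm2) -> Tuple[np.ndarray, np.ndarray]:
    """Amplitude and phase (1..8) from the RMM components.

    Returns (amplitude, phase); phase is 0 (undefined) where the amplitude
    is zero.  Boundaries are half-open in the counterclockwise direction.
    """
    r1 = np.asarray(rmm1, dtype=float)
    r2 = np.asarray(rmm2, dtype=float)
    amp = np.hypot(r1, r2)
    angle = np.degrees(np.arctan2(r2, r1)) % 360.0
    phase = (np.floor(((angle - 180.0) % 360.0) / 45.0).astype(int) + 1).astype(int)
    phase = np.where(amp > 0, phase, 0)
    if amp.ndim == 0:
        return float(amp), int(phase)
    return amp, phase


def rmm_series(dates, rmm1, rmm2) -> pd.DataFrame:
    """Assemble the canonical RMM table: date, RMM1/2, amplitude, phase, active."""
    idx = require_daily(dates, "RMM date axis")
    amp, phase = amplitude_phase(rmm1, rmm2)
    return pd.DataFrame(
        {
            "date": idx,
            "rmm1": np.asarray(rmm1, dtype=float),
            "rmm2": np.asarray(rmm2, dtype=float),
            "amplitude": amp,
            "phase": phase,
            "active": amp >= ACTIVE_AMPLITUDE,
        }
    )


def read_rmm(path) -> pd.DataFrame:
    """Read a delimited text table with columns date, RMM1, RMM2."""
    raw = pd.read_csv(path, sep=None, engine="python")
    raw.columns = [c.strip().lower() for c in raw.columns]
    return rmm_series(pd.to_datetime(raw["date"]), raw["rmm1"], raw["rmm2"])


def write_rmm(series: pd.DataFrame, path) -> None:
    series[["date", "rmm1", "rmm2"]].to_csv(path, index=False)


def _qualifying(series: pd.DataFrame, criteria: StallCriteria) -> np.ndarray:
    ok = series["phase"].isin(list(criteria.phase_set)).to_numpy()
    if criteria.require_active:
        ok = ok & series["active"].to_numpy()
    return ok


def residence_time(series: pd.DataFrame, criteria: StallCriteria = StallCriteria()) -> int:
    """Longest run of consecutive days inside the phase set (days).

    Alternation between phases within the set does not break a run; a
    non-qualifying stretch breaks it unless it is at most ``max_gap_days``
    long, in which case the bridged span (gap days included) counts as one
    run.  With ``require_active`` set, inactive days do not qualify.
    """
    if len(series) == 0:
        raise ValueError("empty RMM series")
    require_daily(series["date"], "RMM date axis")
    ok = _qualifying(series, criteria)
    # collect maximal qualifying runs as (start, end) index pairs
    runs = []
    start = None
    for i, flag in enumerate(ok):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(ok) - 1))
    if not runs:
        return 0
    # bridge runs separated by gaps of at most max_gap_days
    merged = [runs[0]]
    for s, e in runs[1:]:
        ps, pe = merged[-1]
        if s - pe - 1 <= criteria.max_gap_days:
            merged[-1] = (ps, e)
        else:
            merged.append((s, e))
    return max(e - s + 1 for s, e in merged)


def classify_members(
    member_rmm: Mapping, criteria: StallCriteria = StallCriteria()
) -> pd.DataFrame:
    """Split ensemble members into stalled / fast / neither by MJO residence.

    ``member_rmm`` maps a member key (or (model, member) tuple) to its RMM
    forecast table.  Residence >= stall_min_days is "stalled"; residence
    < fast_max_days is "fast"; the band in between is "neither", so the two
    subsets can never overlap.
    """
    rows = []
    for key, series in member_rmm.items():
        res = residence_time(series, criteria)
        if res >= criteria.stall_min_days:
            cat = "stalled"
        elif res < criteria.fast_max_days:
            cat = "fast"
        else:
            cat = "neither"
        rows.append({"member": key, "residence_days": res, "category": cat})
    return pd.DataFrame(rows)


def _smoothed_calendar_mean(clim_source: xr.DataArray, smoothing_days: int) -> xr.DataArray:
    """Calendar-day mean climatology, smoothed by a wrapping running mean."""
    doy = doy365(clim_source["time"].values)
    clim = (
        clim_source.assign_coords(dayofyear=("time", doy))
        .groupby("dayofyear")
        .mean("time")
    )
    # fill any calendar days absent from the source before smoothing
    full = clim.reindex(dayofyear=np.arange(1, DAYS_PER_YEAR + 1))
    half = (smoothing_days - 1) // 2
    padded = xr.concat(
        [full.isel(dayofyear=slice(-half, None)), full,
         full.isel(dayofyear=slice(None, half))],
        dim="dayofyear",
    )
    smoothed = (
        padded.rolling(dayofyear=smoothing_days, center=True, min_periods=1)
        .mean()
        .isel(dayofyear=slice(half, half + DAYS_PER_YEAR))
    )
    return smoothed.assign_coords(dayofyear=np.arange(1, DAYS_PER_YEAR + 1))


def anomaly_vs_smoothed_clim(
    field: xr.DataArray,
    clim_source: xr.DataArray,
    smoothing_days: int = 11,
) -> xr.DataArray:
    """Anomalies of ``field`` against a smoothed calendar-day climatology.

    The climatology is the per-calendar-day mean of ``clim_source`` (a
    multi-year record or a pooled hindcast with a member dimension),
    smoothed with a centered running mean that wraps the year boundary.
    """
    if smoothing_days % 2 == 0 or smoothing_days < 1:
        raise ValueError("smoothing window must be odd and >= 1")
    src = clim_source
    if "member" in src.dims:
        src = src.mean("member")
    clim = _smoothed_calendar_mean(src, smoothing_days)
    doy = doy365(field["time"].values)
    clim_on_times = clim.isel(dayofyear=xr.DataArray(doy - 1, dims="time"))
    clim_on_times = clim_on_times.assign_coords(time=field["time"]).drop_vars(
        "dayofyear"
    )
    if clim_on_times.isnull().any():
        raise ValueError("climatology source does not cover the field's calendar days")
    out = field - clim_on_times
    out.attrs = dict(field.attrs)
    out.attrs["climatology_smoothing_days"] = smoothing_days
    return out


def weighted_composite(
    member_fields: Mapping[str, xr.DataArray],
    subset: pd.DataFrame,
    category: str,
    config: CompositeConfig = CompositeConfig(),
) -> xr.DataArray:
    """Equal-per-model composite of anomaly fields for one member subset.

    ``member_fields`` maps model_id to an anomaly cube with a member
    dimension; ``subset`` is a classification table from
    :func:`classify_members` whose member keys are (model_id, member_index)
    tuples.  Within each model the selected members are averaged; models
    contributing at least one member are then averaged with equal weight
    (so a model with 10 members counts the same as a model with 1); finally
    the result is averaged over the config time window.
    """
    chosen = subset[subset["category"] == category]
    if chosen.empty:
        raise ValueError(f"no members in subset {category!r}")
    per_model = []
    counts: Dict[str, int] = {}
    for model_id, cube in member_fields.items():
        idx = [m for (mod, m) in chosen["member"] if mod == model_id]
        if not idx:
            continue
        counts[model_id] = len(idx)
        per_model.append(cube.sel(member=idx).mean("member"))
    if not per_model:
        raise ValueError(f"no model contributes members to subset {category!r}")
    comp = xr.concat(per_model, dim="model").mean("model")
    comp = comp.sel(time=slice(config.window_start, config.window_end)).mean("time")
    comp.attrs.update(
        subset=category,
        n_models=len(per_model),
        subset_sizes=str(counts),
        window=f"{config.window_start}..{config.window_end}",
        weighting="equal-per-model",
    )
    return comp
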