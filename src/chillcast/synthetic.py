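"""Synthetic gridded weather with an embedded compound extreme event.

Generates every input the analysis pipeline consumes, with known ground
truth: daily rain/temperature/wind observations carrying a week-long
quasi-stationary-low signature (heavy rain, depressed daytime temperature,
elevated wind), ensemble forecasts of tunable skill, multi-year multi-member
hindcasts, RMM phase-space trajectories with controllable angular speed (to
create MJO stalls), and MSLP anomaly fields coupled to the MJO state.

Design choices: background rain is a wet-day Bernoulli times an exponential
intensity (zero-inflated like real tropical rainfall); the event footprint is
Gaussian in space and top-hat in time so onset/offset dates are sharp and the
duration is exactly recoverable; each variable draws from its own RNG stream
derived from the master seed, so changing one variable's parameters never
perturbs the others.  Dates use the proleptic Gregorian calendar with real
leap days.  No dynamical realism (no pressure-wind balance, no advection) is
attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Optional

import numpy as np
import pandas as pd
import xarray as xr

from ._calendar import doy365
from .mjo import rmm_series

__all__ = [
    "GridConfig",
    "BackgroundConfig",
    "EventConfig",
    "EnsembleConfig",
    "HindcastConfig",
    "SyntheticConfig",
    "gen_observations",
    "gen_ensemble",
    "gen_hindcast",
    "gen_rmm",
    "gen_mslp_anomalies",
]

# fixed per-variable offsets into the master seed: changing one variable's
# parameters must not perturb the draws of the others
_STREAMS = {
    "temp": 11,
    "rain_occurrence": 12,
    "rain_intensity": 13,
    "wind": 14,
    "ensemble": 15,
    "hindcast": 16,
    "rmm": 17,
    "mslp": 18,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STREAMS[stream]])


@dataclass(frozen=True)
class GridConfig:
    """Regular lat/lon grid covering the inland Gulf box by default."""

    n_lat: int = 11
    n_lon: int = 17
    lat_min: float = -23.0
    lat_max: float = -18.0
    lon_min: float = 137.0
    lon_max: float = 145.0

    def __post_init__(self) -> None:
        if self.n_lat < 1 or self.n_lon < 1:
            raise ValueError("grid sizes must be positive")

    @property
    def lat(self) -> np.ndarray:
        return np.linspace(self.lat_min, self.lat_max, self.n_lat)

    @property
    def lon(self) -> np.ndarray:
        return np.linspace(self.lon_min, self.lon_max, self.n_lon)


@dataclass(frozen=True)
class BackgroundConfig:
    """Stationary seasonal background climate (tropical-summer defaults).

    Temperature follows a sinusoidal annual cycle (southern-hemisphere
    phase: maximum in mid-January) plus Gaussian daily noise; rain is
    Bernoulli wet days with exponential intensities; wind is Weibull with
    shape 2 (Rayleigh-like, as for daily mean surface wind).
    """

    temp_mean: float = 28.0  # degC annual mean
    temp_amplitude: float = 7.0  # degC seasonal half-range
    temp_noise: float = 2.0  # degC daily standard deviation
    wet_day_prob: float = 0.30
    rain_scale: float = 8.0  # mm/day mean wet-day intensity
    wind_scale: float = 3.5  # m/s Weibull scale
    wind_shape: float = 2.0


@dataclass(frozen=True)
class EventConfig:
    """A week-long stationary low: cold, wet and windy around a fixed center.

    The footprint is ``exp(-0.5 (d / radius)^2)`` in great-circle-free
    lat/lon degrees and a top-hat in time over [onset, onset+duration).
    Default amplitudes mirror the February 2019 Gulf event scale: tens of
    mm/day of extra rain, a ~10 degC daytime-temperature drop, and a strong
    wind increase at the center.
    """

    onset: str = "2019-01-30"
    duration: int = 9  # days
    center_lat: float = -20.5
    center_lon: float = 141.0
    radius: float = 2.5  # degrees
    rain_amplitude: float = 60.0  # mm/day at center
    temp_depression: float = 10.0  # degC at center
    wind_increase: float = 6.0  # m/s at center

    def __post_init__(self) -> None:
        if self.duration < 1:
            raise ValueError("event duration must be >= 1 day")
        if not self.radius > 0:
            raise ValueError("event radius must be positive")

    @property
    def dates(self) -> pd.DatetimeIndex:
        start = pd.Timestamp(self.onset)
        return pd.date_range(start, start + pd.Timedelta(days=self.duration - 1))


@dataclass(frozen=True)
class EnsembleConfig:
    n_members: int = 33
    skill: float = 0.7
    noise_scale_rain: float = 6.0  # mm/day
    noise_scale_temp: float = 1.5  # degC
    noise_scale_wind: float = 1.0  # m/s

    def __post_init__(self) -> None:
        if self.n_members < 1:
            raise ValueError("n_members must be >= 1")
        if not 0.0 <= self.skill <= 1.0:
            raise ValueError("skill must lie in [0, 1]")


@dataclass(frozen=True)
class HindcastConfig:
    n_years: int = 23
    n_members: int = 11
    first_year: int = 1990
    init_dates_per_month: tuple = (1, 9, 17, 25)


@dataclass(frozen=True)
class SyntheticConfig:
    """Full generator configuration; the defaults define the study conditions."""

    grid: GridConfig = field(default_factory=GridConfig)
    start: str = "2015-01-01"
    end: str = "2019-12-31"
    seed: int = 0
    background: BackgroundConfig = field(default_factory=BackgroundConfig)
    event: Optional[EventConfig] = field(default_factory=EventConfig)
    ensemble: EnsembleConfig = field(default_factory=EnsembleConfig)
    hindcast: HindcastConfig = field(default_factory=HindcastConfig)

    def __post_init__(self) -> None:
        start, end = pd.Timestamp(self.start), pd.Timestamp(self.end)
        if start > end:
            raise ValueError("reversed date range")
        if self.event is not None:
            ev = self.event.dates
            if ev[0] < start or ev[-1] > end:
                raise ValueError("event window must lie inside the date range")

    @property
    def times(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start, self.end, freq="D")

    def without_event(self) -> "SyntheticConfig":
        return replace(self, event=None)


def _cube(values, times, grid: GridConfig, units: str, name: str) -> xr.DataArray:
    return xr.DataArray(
        values,
        dims=("time", "lat", "lon"),
        coords={"time": times, "lat": grid.lat, "lon": grid.lon},
        name=name,
        attrs={"units": units},
    )


def _footprint(event: EventConfig, grid: GridConfig) -> np.ndarray:
    lat2, lon2 = np.meshgrid(grid.lat, grid.lon, indexing="ij")
    d2 = (lat2 - event.center_lat) ** 2 + (lon2 - event.center_lon) ** 2
    return np.exp(-0.5 * d2 / event.radius**2)


def background_temperature(times, bg: BackgroundConfig) -> np.ndarray:
    """Deterministic seasonal-cycle temperature (no noise), degC."""
    doy = doy365(times)
    # SH summer: annual maximum on 15 January (day 15)
    return bg.temp_mean + bg.temp_amplitude * np.cos(2 * np.pi * (doy - 15) / 365.0)


def _background_fields(times, grid: GridConfig, bg: BackgroundConfig, seed: int):
    shape = (len(times), grid.n_lat, grid.n_lon)
    temp = background_temperature(times, bg)[:, None, None] + _rng(
        seed, "temp"
    ).normal(0.0, bg.temp_noise, shape)
    wet = _rng(seed, "rain_occurrence").random(shape) < bg.wet_day_prob
    intensity = _rng(seed, "rain_intensity").exponential(bg.rain_scale, shape)
    rain = np.where(wet, intensity, 0.0)
    wind = _rng(seed, "wind").weibull(bg.wind_shape, shape) * bg.wind_scale
    return rain, temp, wind


def gen_observations(config: SyntheticConfig):
    """Daily (rain, temp, wind) cubes: seasonal background plus the event bump.

    The event adds a deterministic Gaussian-in-space, top-hat-in-time bump
    (rain up, temperature down, wind up), so for a fixed seed the difference
    between an event run and the background-only run is exactly the bump.
    Rain is clipped at zero; outputs are bit-reproducible for a fixed seed.
    """
    times = config.times
    rain, temp, wind = _background_fields(
        times, config.grid, config.background, config.seed
    )
    if config.event is not None:
        ev = config.event
        foot = _footprint(ev, config.grid)
        in_event = times.isin(ev.dates)
        rain[in_event] += ev.rain_amplitude * foot
        temp[in_event] -= ev.temp_depression * foot
        wind[in_event] += ev.wind_increase * foot
    rain = np.maximum(rain, 0.0)
    return (
        _cube(rain, times, config.grid, "mm/day", "rain"),
        _cube(temp, times, config.grid, "degC", "temp"),
        _cube(wind, times, config.grid, "m/s", "wind"),
    )


def gen_ensemble(
    truth: xr.DataArray,
    n_members: int,
    skill: float,
    noise_scale: float,
    init_date,
    seed: int,
    background: Optional[xr.DataArray] = None,
    model_id: str = "synthetic",
    clip_min: Optional[float] = None,
) -> xr.DataArray:
    """Ensemble forecast of ``truth``: members blend truth with climatology.

    member_m = skill * truth + (1 - skill) * background + noise, with iid
    Gaussian noise of standard deviation ``noise_scale`` per member.  At
    skill 1 and noise 0 every member equals the truth.  ``background``
    defaults to the time-mean of the truth broadcast along time (a crude
    climatological forecast).  ``clip_min`` floors the members (e.g. 0 for
    rain or wind, whose noise would otherwise go negative).
    """
    if n_members < 1:
        raise ValueError("n_members must be >= 1")
    if noise_scale < 0:
        raise ValueError("noise_scale must be non-negative")
    init = pd.Timestamp(init_date)
    first = pd.Timestamp(np.asarray(truth["time"].values).min())
    if init > first:
        raise ValueError("init_date must not be after the first forecast day")
    if background is None:
        background = truth.mean("time").broadcast_like(truth)
    base = skill * truth + (1.0 - skill) * background
    rng = _rng(seed, "ensemble")
    noise = rng.normal(0.0, noise_scale, (n_members,) + truth.shape)
    values = base.values[None, ...] + noise
    if clip_min is not None:
        values = np.maximum(values, clip_min)
    out = xr.DataArray(
        values,
        dims=("member",) + truth.dims,
        coords={"member": np.arange(n_members), **{d: truth[d] for d in truth.dims}},
        name=truth.name,
        attrs=dict(truth.attrs),
    )
    out = out.assign_coords(
        init_date=("member", np.repeat(np.datetime64(init, "ns"), n_members))
    )
    out.attrs.update(model_id=model_id, is_hindcast=0)
    return out


def gen_hindcast(config: SyntheticConfig, variable: str = "rain"):
    """Multi-year, multi-member hindcasts with stationary background statistics.

    Returns one ensemble cube per hindcast year, each spanning that full
    calendar year with ``hindcast.n_members`` exchangeable members drawn from
    the background distribution (no embedded event).  Pooling all years and
    members therefore gives n_years x n_members member-days per calendar day
    before any windowing.
    """
    hc = config.hindcast
    if hc.n_years < 2:
        raise ValueError("need n_years >= 2 to build a multi-year percentile")
    var_index = {"rain": 0, "temp": 1, "wind": 2}
    if variable not in var_index:
        raise ValueError(f"unknown variable {variable!r}")
    units = {"rain": "mm/day", "temp": "degC", "wind": "m/s"}[variable]
    cubes = []
    for year_offset in range(hc.n_years):
        year = hc.first_year + year_offset
        times = pd.date_range(f"{year}-01-01", f"{year}-12-31", freq="D")
        members = []
        for m in range(hc.n_members):
            # distinct stream per (year, member), derived from the master seed
            sub = np.random.default_rng(
                [int(config.seed), _STREAMS["hindcast"], year, m]
            )
            member_seed = int(sub.integers(0, 2**31 - 1))
            fields = _background_fields(
                times, config.grid, config.background, member_seed
            )
            members.append(fields[var_index[variable]])
        values = np.stack(members, axis=0)
        if variable == "rain":
            values = np.maximum(values, 0.0)
        da = xr.DataArray(
            values,
            dims=("member", "time", "lat", "lon"),
            coords={
                "member": np.arange(hc.n_members),
                "time": times,
                "lat": config.grid.lat,
                "lon": config.grid.lon,
            },
            name=variable,
            attrs={"units": units, "is_hindcast": 1, "hindcast_year": year,
                   "model_id": "synthetic"},
        )
        cubes.append(da)
    return cubes


def gen_rmm(
    date_range,
    angular_speed_fn: Callable,
    amplitude_fn: Callable,
    seed: int = 0,
    theta0_deg: float = 0.0,
    noise: float = 0.0,
) -> pd.DataFrame:
    """RMM1/RMM2 trajectory with controllable phase-space angular speed.

    (RMM1, RMM2) = amplitude(t) * (cos theta(t), sin theta(t)) with theta
    integrated forward from ``theta0_deg`` at ``angular_speed_fn(date)``
    degrees/day (counterclockwise, i.e. in the direction of increasing phase
    number), plus optional Gaussian noise on both components.  Setting the
    angular speed to zero over a sub-window with amplitude > 1 creates an
    active stall of exactly that sub-window's length.
    """
    dates = pd.DatetimeIndex(date_range)
    if len(dates) == 0:
        raise ValueError("empty date range")
    amp = np.array([float(amplitude_fn(d)) for d in dates])
    if np.any(amp < 0):
        raise ValueError("amplitude_fn must be non-negative")
    speed = np.array([float(angular_speed_fn(d)) for d in dates])
    theta = np.deg2rad(theta0_deg + np.concatenate([[0.0], np.cumsum(speed[:-1])]))
    rmm1 = amp * np.cos(theta)
    rmm2 = amp * np.sin(theta)
    if noise > 0:
        rng = _rng(seed, "rmm")
        rmm1 = rmm1 + rng.normal(0.0, noise, len(dates))
        rmm2 = rmm2 + rng.normal(0.0, noise, len(dates))
    return rmm_series(dates, rmm1, rmm2)


def gen_mslp_anomalies(
    rmm: pd.DataFrame,
    grid: GridConfig,
    coupling: float,
    seed: int = 0,
    noise: float = 1.0,
    center_lat: float = -20.5,
    center_lon: float = 141.0,
    radius: float = 4.0,
) -> xr.DataArray:
    """Daily MSLP anomaly fields (hPa) coupled to the MJO state.

    On days when the MJO is active in phases 6-7, a Gaussian low of depth
    ``coupling`` hPa per unit amplitude is imprinted at the fixed center;
    the trajectory-mean signal is removed so the output is an anomaly with
    zero time mean by construction, plus white noise.  Coupling 0 gives
    pure noise.
    """
    if coupling < 0 or noise < 0:
        raise ValueError("coupling and noise must be non-negative")
    dates = pd.DatetimeIndex(rmm["date"].to_numpy())
    lat2, lon2 = np.meshgrid(grid.lat, grid.lon, indexing="ij")
    d2 = (lat2 - center_lat) ** 2 + (lon2 - center_lon) ** 2
    bump = np.exp(-0.5 * d2 / radius**2)
    in_phase = rmm["phase"].isin([6, 7]).to_numpy() & rmm["active"].to_numpy()
    depth = np.where(in_phase, -coupling * rmm["amplitude"].to_numpy(), 0.0)
    signal = depth[:, None, None] * bump[None, :, :]
    signal = signal - signal.mean(axis=0, keepdims=True)
    rng = _rng(seed, "mslp")
    values = signal + rng.normal(0.0, noise, signal.shape)
    return _cube(values, dates, grid, "hPa", "mslp_anomaly")
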