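"""End-to-end orchestration of the chill-analysis pipeline on synthetic data.

``run_pipeline`` wires the stages together the way the event study is laid
out: generate observations with the embedded compound event, compute the
chill cube, build multi-year calendar-day percentile climatologies, flag
exceedances and summarise event runs over the Gulf box, turn lagged ensemble
forecasts into probability-of-extreme maps for the target week, and classify
ensemble members by MJO stalling with the associated MSLP-anomaly composites.
Every artifact is written to the output directory with provenance attributes;
the whole run is a pure function of (config, seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
import xarray as xr
import yaml

from .chill import ChillParams, chill_index, chill_cube
from .climatology import (
    CalendarClimatology,
    RegionBox,
    area_average,
    area_fraction_exceeding,
    calendar_percentile,
    exceedance_mask,
    longest_run,
)
from .ensemble import assemble_lagged_ensemble, prob_extreme
from .io import write_cube
from .mjo import (
    CompositeConfig,
    StallCriteria,
    classify_members,
    residence_time,
    weighted_composite,
)
from .synthetic import SyntheticConfig, gen_ensemble, gen_mslp_anomalies, gen_observations, gen_rmm

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("chillcast")


@dataclass(frozen=True)
class PipelineConfig:
    """Settings for a full synthetic-event analysis run."""

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    region: RegionBox = field(default_factory=RegionBox)
    percentile_window: int = 15
    q_chill: float = 0.9
    q_rain: float = 0.9
    q_wind: float = 0.9
    q_temp_cold: float = 0.1
    q_temp_hot: float = 0.9
    target_window: Tuple[str, str] = ("2019-01-31", "2019-02-06")
    members_per_day: int = 33
    lagged_days: int = 3
    forecast_init: str = "2019-01-24"  # lead week 1
    forecast_skill: float = 0.6
    prob_mode: str = "weekly_mean"
    stall: StallCriteria = field(default_factory=StallCriteria)
    composite: CompositeConfig = field(default_factory=CompositeConfig)
    mjo_models: Tuple[Tuple[str, int], ...] = (
        ("modelA", 10),
        ("modelB", 10),
        ("modelC", 5),
    )
    mslp_coupling: float = 4.0  # hPa per unit MJO amplitude
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        if "synthetic" in kwargs:
            kwargs["synthetic"] = _synthetic_from_dict(kwargs["synthetic"])
        if "region" in kwargs:
            kwargs["region"] = RegionBox(**kwargs["region"])
        if "stall" in kwargs:
            st = dict(kwargs["stall"])
            if "phase_set" in st:
                st["phase_set"] = frozenset(st["phase_set"])
            kwargs["stall"] = StallCriteria(**st)
        if "composite" in kwargs:
            kwargs["composite"] = CompositeConfig(**kwargs["composite"])
        if "target_window" in kwargs:
            kwargs["target_window"] = tuple(kwargs["target_window"])
        if "mjo_models" in kwargs:
            kwargs["mjo_models"] = tuple(tuple(m) for m in kwargs["mjo_models"])
        return cls(**kwargs)


def _synthetic_from_dict(raw: dict) -> SyntheticConfig:
    from .synthetic import (
        BackgroundConfig,
        EnsembleConfig,
        EventConfig,
        GridConfig,
        HindcastConfig,
    )

    kwargs = dict(raw)
    for key, cls in (
        ("grid", GridConfig),
        ("background", BackgroundConfig),
        ("event", EventConfig),
        ("ensemble", EnsembleConfig),
        ("hindcast", HindcastConfig),
    ):
        if key in kwargs and kwargs[key] is not None:
            kwargs[key] = cls(**kwargs[key])
    return SyntheticConfig(**kwargs)


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(dataclasses.asdict(config), default=str, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _series_climatology(series: xr.DataArray, q: float, window: int) -> CalendarClimatology:
    """Calendar-day percentile of a 1-D daily series (single virtual cell)."""
    cube = series.expand_dims(lat=[0.0], lon=[0.0]).transpose("time", "lat", "lon")
    return calendar_percentile(cube, q=q, window=window)


def _series_exceedance(series: xr.DataArray, clim: CalendarClimatology, direction: str) -> xr.DataArray:
    cube = series.expand_dims(lat=[0.0], lon=[0.0]).transpose("time", "lat", "lon")
    return exceedance_mask(cube, clim, direction=direction).isel(lat=0, lon=0, drop=True)


def _member_chill(rain_e: xr.DataArray, temp_e: xr.DataArray, wind_e: xr.DataArray,
                  params: ChillParams) -> xr.DataArray:
    values = chill_index(wind_e.values, temp_e.values, rain_e.values, params)
    out = xr.DataArray(values, coords=rain_e.coords, dims=rain_e.dims, name="chill_index")
    out.attrs = {"units": "kJ/m2/h"}
    if "init_date" in rain_e.coords:
        out = out.assign_coords(init_date=rain_e["init_date"])
    return out


def _forecast_ensembles(config: PipelineConfig, truth: Dict[str, xr.DataArray]) -> xr.DataArray:
    """Lagged chill-index ensemble for the target window (per-variable blend)."""
    noise = {
        "rain": config.synthetic.ensemble.noise_scale_rain,
        "temp": config.synthetic.ensemble.noise_scale_temp,
        "wind": config.synthetic.ensemble.noise_scale_wind,
    }
    end = pd.Timestamp(config.target_window[1])
    runs = {"rain": [], "temp": [], "wind": []}
    for lag in range(config.lagged_days):
        init = pd.Timestamp(config.forecast_init) - pd.Timedelta(days=lag)
        for var in runs:
            sub_truth = truth[var].sel(time=slice(init, end))
            runs[var].append(
                gen_ensemble(
                    sub_truth,
                    n_members=config.members_per_day,
                    skill=config.forecast_skill,
                    noise_scale=noise[var],
                    init_date=init,
                    seed=config.seed + 1000 + lag,
                    clip_min=None if var == "temp" else 0.0,
                )
            )
    lagged = {var: assemble_lagged_ensemble(r) for var, r in runs.items()}
    return _member_chill(lagged["rain"], lagged["temp"], lagged["wind"], ChillParams())


def _mjo_stage(config: PipelineConfig, outdir: Path) -> dict:
    """Observed stalled trajectory, member classification, MSLP composites."""
    dates = pd.date_range("2019-01-20", "2019-03-05", freq="D")
    stall_start, stall_len = pd.Timestamp("2019-01-29"), 18

    def _stalling_trajectory(stop_days: int, amp_active: float):
        """Speed/amplitude functions: active stall of exactly stop_days in
        phases 6-7, weak (inactive) elsewhere along the circuit."""
        stop_end = stall_start + pd.Timedelta(days=stop_days)

        def speed(d):
            return 0.0 if stall_start <= d < stop_end else 9.0

        def amplitude(d):
            return amp_active if stall_start <= d < stop_end else 0.8

        return speed, amplitude

    # start angle chosen so the trajectory sits at the phase-6 center when
    # the stall begins (9 deg/day transit from the series start)
    theta0 = 67.5 - 9.0 * (stall_start - dates[0]).days
    obs_speed, obs_amp = _stalling_trajectory(stall_len, 1.5)
    obs_rmm = gen_rmm(dates, obs_speed, obs_amp, seed=config.seed, theta0_deg=theta0)
    obs_rmm.to_csv(outdir / "rmm_observed.csv", index=False)

    rng = np.random.default_rng([int(config.seed), 77])
    member_rmm = {}
    member_fields: Dict[str, xr.DataArray] = {}
    for model_id, n_members in config.mjo_models:
        fields = []
        for m in range(n_members):
            stop = int(rng.integers(4, 23))  # predicted residence spread
            speed, amp = _stalling_trajectory(stop, 1.4)
            series = gen_rmm(
                dates, speed, amp,
                seed=int(rng.integers(0, 2**31 - 1)), theta0_deg=theta0,
            )
            member_rmm[(model_id, m)] = series
            fields.append(
                gen_mslp_anomalies(
                    series, config.synthetic.grid, coupling=config.mslp_coupling,
                    seed=int(rng.integers(0, 2**31 - 1)),
                )
            )
        member_fields[model_id] = xr.concat(
            fields, dim=pd.Index(range(n_members), name="member")
        )
    classification = classify_members(member_rmm, config.stall)
    counts = classification["category"].value_counts().to_dict()
    log.info("MJO member classification: %s", counts)
    classification_out = classification.copy()
    classification_out["member"] = ["/".join(map(str, k)) for k in classification_out["member"]]
    classification_out.to_json(outdir / "mjo_classification.json", orient="records")

    composites = {}
    for cat in ("stalled", "fast"):
        if (classification["category"] == cat).any():
            comp = weighted_composite(member_fields, classification, cat, config.composite)
            write_cube(comp.expand_dims(time=[pd.Timestamp(config.composite.window_start)]),
                       outdir / f"mslp_composite_{cat}.nc", name="mslp_anomaly")
            composites[cat] = comp
    return {
        "observed_rmm": obs_rmm,
        "observed_residence_days": residence_time(obs_rmm, config.stall),
        "classification": classification,
        "composites": composites,
    }


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run every stage on synthetic data; returns the in-memory artifacts.

    Writes NetCDF cubes, CSV series and JSON summaries under ``outdir``.
    Deterministic: the same config and seed give byte-identical numbers.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_hash = _config_hash(config)
    synth = dataclasses.replace(config.synthetic, seed=config.seed)

    log.info("stage 1: synthetic observations (%s..%s)", synth.start, synth.end)
    rain, temp, wind = gen_observations(synth)
    chill = chill_cube(rain, temp, wind)
    for cube, fname in ((rain, "rain.nc"), (temp, "temp.nc"), (wind, "wind.nc"),
                        (chill, "chill.nc")):
        cube.attrs["config_hash"] = cfg_hash
        write_cube(cube, outdir / fname)

    log.info("stage 2: calendar-day percentile climatologies (window=%d)",
             config.percentile_window)
    clims = {
        "chill": calendar_percentile(chill, config.q_chill, config.percentile_window),
        "rain": calendar_percentile(rain, config.q_rain, config.percentile_window),
        "wind": calendar_percentile(wind, config.q_wind, config.percentile_window),
        "temp_cold": calendar_percentile(temp, config.q_temp_cold, config.percentile_window),
        "temp_hot": calendar_percentile(temp, config.q_temp_hot, config.percentile_window),
    }
    for name, clim in clims.items():
        clim.to_dataset().to_netcdf(outdir / f"clim_{name}.nc", engine="scipy")

    log.info("stage 3: exceedance masks and Gulf-average event summaries")
    masks = {
        "chill": exceedance_mask(chill, clims["chill"], "above"),
        "rain": exceedance_mask(rain, clims["rain"], "above"),
        "wind": exceedance_mask(wind, clims["wind"], "above"),
        "temp_cold": exceedance_mask(temp, clims["temp_cold"], "below"),
    }
    chill_series = area_average(chill, config.region)
    rain_series = area_average(rain, config.region)
    series_clim = _series_climatology(chill_series, config.q_chill, config.percentile_window)
    rain_series_clim = _series_climatology(rain_series, config.q_rain, config.percentile_window)
    chill_mask_series = _series_exceedance(chill_series, series_clim, "above")
    rain_mask_series = _series_exceedance(rain_series, rain_series_clim, "above")
    summaries = {
        "chill": longest_run(chill_mask_series, chill_series),
        "rain": longest_run(rain_mask_series, rain_series),
    }
    pd.DataFrame(
        {"date": chill_series["time"].values,
         "chill_gulf_mean": chill_series.values,
         "rain_gulf_mean": rain_series.values,
         "chill_extreme": chill_mask_series.values,
         "rain_extreme": rain_mask_series.values}
    ).to_csv(outdir / "gulf_series.csv", index=False)

    log.info("stage 4: lagged ensemble probability map (init %s, %d x %d members)",
             config.forecast_init, config.members_per_day, config.lagged_days)
    chill_forecast = _forecast_ensembles(config, {"rain": rain, "temp": temp, "wind": wind})
    pmap = prob_extreme(chill_forecast, clims["chill"], config.target_window,
                        mode=config.prob_mode)
    pmap.attrs["config_hash"] = cfg_hash
    write_cube(pmap.expand_dims(time=[pd.Timestamp(config.target_window[0])]),
               outdir / "prob_extreme_chill.nc", name="prob_extreme")
    gulf_frac = float(
        area_fraction_exceeding((pmap > 0.0).astype(bool), config.region).values
    )

    log.info("stage 5: MJO stall classification and MSLP composites")
    mjo_art = _mjo_stage(config, outdir)

    summary = {
        "config_hash": cfg_hash,
        "event_runs": {
            name: {
                "onset": str(s.onset.date()) if s.onset is not None else None,
                "offset": str(s.offset.date()) if s.offset is not None else None,
                "duration_days": s.duration,
                "peak_value": s.peak_value,
                "peak_date": str(s.peak_date.date()) if s.peak_date is not None else None,
            }
            for name, s in summaries.items()
        },
        "prob_extreme": {
            "mode": config.prob_mode,
            "n_members": int(pmap.attrs["n_members"]),
            "gulf_fraction_nonzero": gulf_frac,
            "gulf_mean_probability": float(area_average(pmap, config.region).values),
        },
        "mjo": {
            "observed_residence_days": int(mjo_art["observed_residence_days"]),
            "subset_sizes": mjo_art["classification"]["category"]
            .value_counts()
            .to_dict(),
        },
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=str)
    return {
        "rain": rain, "temp": temp, "wind": wind, "chill": chill,
        "climatologies": clims, "masks": masks, "summaries": summaries,
        "chill_series": chill_series, "prob_map": pmap, "mjo": mjo_art,
        "summary": summary,
    }
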