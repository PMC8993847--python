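"""Livestock chill index: an empirical heat-loss model for exposed livestock.

The index estimates the potential heat loss C (kJ/m^2/h) of newborn lambs and
newly-shorn sheep from daily mean wind speed v (m/s), daily average
temperature T (degC) and daily rainfall R (mm):

    C = (11.7 + 3.1 * v**0.5) * (40 - T) + 481 + 418 * (1 - exp(-0.04 * R))

The wind-temperature term grows with wind and with the departure of T below
the 40 degC reference; the rain term saturates at 418 kJ/m^2/h for heavy rain.
Operational alert categories: C >= 1000 is "high" (sheep-grazier alert level)
and C >= 1200 is "severe".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import xarray as xr

__all__ = [
    "ChillParams",
    "HIGH_THRESHOLD",
    "SEVERE_THRESHOLD",
    "chill_index",
    "chill_cube",
    "classify_chill",
]

#: Alert category boundaries (kJ/m^2/h).  Both are closed on the left:
#: C >= 1000 is "high", C >= 1200 is "severe", so an operational alert
#: triggers at exactly the published threshold.
HIGH_THRESHOLD = 1000.0
SEVERE_THRESHOLD = 1200.0

log = logging.getLogger("chillcast")

# canonical spellings for the units the three input cubes must declare
_UNIT_ALIASES = {
    "mm/day": "mm/day",
    "mm day-1": "mm/day",
    "mm": "mm/day",
    "degc": "degC",
    "deg_c": "degC",
    "celsius": "degC",
    "c": "degC",
    "m/s": "m/s",
    "m s-1": "m/s",
    "kj/m2/h": "kJ/m2/h",
}


@dataclass(frozen=True)
class ChillParams:
    """Constants of the chill equation.

    Attributes
    ----------
    base_wind_coeff : kJ/m^2/h per degC at zero wind (11.7).
    wind_coeff : coefficient on v**wind_exponent (3.1).
    wind_exponent : exponent on wind speed (0.5).
    t_ref : reference temperature, degC (40).
    base_rate : constant heat-loss term, kJ/m^2/h (481).
    rain_saturation : asymptotic rain contribution, kJ/m^2/h (418).
    rain_rate : e-folding rate of the rain term, per mm (0.04).
    """

    base_wind_coeff: float = 11.7
    wind_coeff: float = 3.1
    wind_exponent: float = 0.5
    t_ref: float = 40.0
    base_rate: float = 481.0
    rain_saturation: float = 418.0
    rain_rate: float = 0.04

    def __post_init__(self) -> None:
        for name in (
            "base_wind_coeff",
            "wind_coeff",
            "wind_exponent",
            "t_ref",
            "base_rate",
            "rain_saturation",
            "rain_rate",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"ChillParams.{name} must be strictly positive")


_DEFAULT_PARAMS = ChillParams()


def chill_index(wind, temp, rain, params: ChillParams = _DEFAULT_PARAMS):
    """Evaluate the chill equation elementwise.

    Parameters
    ----------
    wind : mean daily wind speed, m/s (>= 0).
    temp : average daily temperature, degC.
    rain : daily rainfall, mm (>= 0).

    Returns the potential heat loss in kJ/m^2/h, broadcast over the inputs.
    Non-finite inputs propagate as NaN.  Temperatures above the reference
    (designed for cold stress) are allowed but trigger a warning since the
    wind-temperature term then contributes negatively.
    """
    v = np.asarray(wind, dtype=float)
    t = np.asarray(temp, dtype=float)
    r = np.asarray(rain, dtype=float)
    if np.any(v[np.isfinite(v)] < 0):
        raise ValueError("wind speed must be non-negative")
    if np.any(r[np.isfinite(r)] < 0):
        raise ValueError("rainfall must be non-negative")
    if np.any(t[np.isfinite(t)] > params.t_ref):
        log.warning(
            "temperature above the %s degC reference: the index was designed "
            "for cold stress and the wind-temperature term turns negative there",
            params.t_ref,
        )
    c = (
        (params.base_wind_coeff + params.wind_coeff * v**params.wind_exponent)
        * (params.t_ref - t)
        + params.base_rate
        + params.rain_saturation * (1.0 - np.exp(-params.rain_rate * r))
    )
    if c.ndim == 0:
        return float(c)
    return c


def _check_units(cube: xr.DataArray, expected: str, name: str) -> None:
    declared = cube.attrs.get("units")
    if declared is None:
        raise ValueError(f"{name} cube has no 'units' attribute (expected {expected})")
    if _UNIT_ALIASES.get(str(declared).lower(), declared) != expected:
        raise ValueError(f"{name} cube has units {declared!r}, expected {expected!r}")


def chill_cube(
    rain: xr.DataArray,
    temp: xr.DataArray,
    wind: xr.DataArray,
    params: ChillParams = _DEFAULT_PARAMS,
) -> xr.DataArray:
    """Grid-point-wise chill index from three aligned daily cubes.

    The cubes must share identical time/lat/lon axes and declare their units
    (mm/day, degC, m/s); a missing value in any input yields a missing value
    in the output at that cell.
    """
    _check_units(rain, "mm/day", "rain")
    _check_units(temp, "degC", "temp")
    _check_units(wind, "m/s", "wind")
    for other, name in ((temp, "temp"), (wind, "wind")):
        if rain.sizes != other.sizes:
            raise ValueError(f"rain and {name} cubes have different shapes")
        for dim in rain.dims:
            if not np.array_equal(rain[dim].values, other[dim].values):
                raise ValueError(f"rain and {name} cubes disagree on the {dim} axis")
    values = chill_index(wind.values, temp.values, rain.values, params)
    out = xr.DataArray(values, coords=rain.coords, dims=rain.dims, name="chill_index")
    out.attrs = {
        "units": "kJ/m2/h",
        "long_name": "livestock chill index (potential heat loss)",
    }
    return out


def classify_chill(c):
    """Classify chill severity: below_high (< 1000), high (>= 1000), severe (>= 1200).

    Boundaries are closed on the left so an alert triggers at exactly the
    published thresholds.
    """
    arr = np.asarray(c, dtype=float)
    out = np.select(
        [arr >= SEVERE_THRESHOLD, arr >= HIGH_THRESHOLD],
        ["severe", "high"],
        default="below_high",
    )
    if arr.ndim == 0:
        return str(out)
    return out
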