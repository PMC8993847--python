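"""Calendar helpers shared by the climatology, ensemble and MJO modules.

All calendar-day statistics use a fixed 365-day calendar: 29 February is
folded onto 28 February (day 59), so every date in a proleptic-Gregorian
record maps to an index in 1..365 and leap-day data is pooled rather than
discarded.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

DAYS_PER_YEAR = 365

# cumulative days before each month in a non-leap year
_MONTH_OFFSET = np.array([0, 31, 59, 90, 120, 151, 181, 212, 243, 273, 304, 334])


def doy365(times) -> np.ndarray:
    """Map dates to a 1..365 calendar-day index, folding Feb 29 onto Feb 28."""
    idx = pd.DatetimeIndex(times)
    doy = _MONTH_OFFSET[idx.month.to_numpy() - 1] + idx.day.to_numpy()
    return np.where((idx.month.to_numpy() == 2) & (idx.day.to_numpy() == 29), 59, doy)


def window_days(day: int, width: int) -> np.ndarray:
    """Calendar days in the centered window of ``width`` around ``day``.

    The window wraps across the year boundary (the window of 1 January
    includes late December).
    """
    if width % 2 == 0 or width < 1:
        raise ValueError(f"window width must be odd and >= 1, got {width}")
    half = (width - 1) // 2
    return (day - 1 + np.arange(-half, half + 1)) % DAYS_PER_YEAR + 1


def require_daily(times, what: str = "time axis") -> pd.DatetimeIndex:
    """Validate a strictly increasing, gap-free daily time axis."""
    idx = pd.DatetimeIndex(times)
    if len(idx) == 0:
        raise ValueError(f"{what} is empty")
    if len(idx) > 1:
        steps = np.diff(idx.to_numpy())
        if not (steps == np.timedelta64(1, "D")).all():
            raise ValueError(f"{what} must be contiguous daily (no gaps, no repeats)")
    return idx
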