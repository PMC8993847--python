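"""Calendar-day percentile thresholds, exceedance masks and run statistics."""

import numpy as np
import pandas as pd
import pytest
import xarray as xr

from chillcast import (
    GULF_REGION,
    RegionBox,
    area_average,
    area_fraction_exceeding,
    calendar_percentile,
    exceedance_mask,
    longest_run,
)

from conftest import make_cube


def brute_force_threshold(cube, q, window, month, day):
    """Independent pooling oracle: explicit date arithmetic, sort-and-index
    quantile with linear interpolation between order statistics."""
    times = pd.DatetimeIndex(cube["time"].values)
    target = pd.Timestamp(2001, month, day)  # any non-leap year as anchor
    half = (window - 1) // 2
    wanted = set()
    for off in range(-half, half + 1):
        d = target + pd.Timedelta(days=off)
        wanted.add((d.month, d.day))
    if (2, 28) in wanted:
        wanted.add((2, 29))  # leap days pool with 28 Feb
    rows = [
        cube.isel(time=i).values
        for i, t in enumerate(times)
        if (t.month, t.day) in wanted
    ]
    pool = np.sort(np.stack(rows), axis=0)
    h = (pool.shape[0] - 1) * q
    lo, frac = int(np.floor(h)), h - np.floor(h)
    hi = min(lo + 1, pool.shape[0] - 1)
    return pool[lo] * (1 - frac) + pool[hi] * frac


def test_matches_brute_force_oracle():
    rng = np.random.default_rng(11)
    times = pd.date_range("2001-01-01", "2003-12-31", freq="D")
    cube = make_cube(rng.normal(size=(len(times), 2, 2)), times=times)
    clim = calendar_percentile(cube, q=0.9, window=15)
    for month, day, doy in [(1, 3, 3), (7, 1, 182), (12, 30, 364), (3, 2, 61)]:
        expected = brute_force_threshold(cube, 0.9, 15, month, day)
        np.testing.assert_allclose(
            clim.thresholds.sel(dayofyear=doy).values, expected, rtol=1e-12
        )
        assert clim.n_pool[doy - 1] == 45  # 15-day window x 3 years


def test_constant_field_gives_constant_threshold():
    times = pd.date_range("2010-01-01", "2012-12-31", freq="D")
    cube = make_cube(np.full((len(times), 1, 1), 3.5), times=times)
    for q in (0.1, 0.5, 0.9):
        clim = calendar_percentile(cube, q=q, window=15)
        np.testing.assert_allclose(clim.thresholds.values, 3.5)


def test_threshold_monotone_in_q_and_order_invariant():
    rng = np.random.default_rng(4)
    cubes = []
    for year in (2001, 2002, 2003):
        times = pd.date_range(f"{year}-01-01", f"{year}-12-31", freq="D")
        cubes.append(make_cube(rng.normal(size=(len(times), 1, 2)), times=times))
    lo = calendar_percentile(cubes, q=0.9, window=5)
    hi = calendar_percentile(cubes, q=0.95, window=5)
    assert (hi.thresholds >= lo.thresholds - 1e-12).all()
    shuffled = calendar_percentile([cubes[2], cubes[0], cubes[1]], q=0.9, window=5)
    np.testing.assert_array_equal(shuffled.thresholds.values, lo.thresholds.values)


def test_input_validation():
    times = pd.date_range("2001-01-01", "2001-12-31", freq="D")
    one_year = make_cube(np.zeros((len(times), 1, 1)), times=times)
    with pytest.raises(ValueError, match="window"):
        calendar_percentile(one_year, q=0.9, window=14)
    with pytest.raises(ValueError, match="years"):
        calendar_percentile(one_year, q=0.9, window=15)
    with pytest.raises(ValueError, match="q"):
        calendar_percentile(one_year, q=1.5, window=15)


def test_leap_day_uses_feb28_threshold():
    times = pd.date_range("2019-01-01", "2021-12-31", freq="D")  # 2020 is leap
    rng = np.random.default_rng(0)
    cube = make_cube(rng.normal(size=(len(times), 1, 1)), times=times)
    clim = calendar_percentile(cube, q=0.9, window=15)
    thr = clim.threshold_for_dates(pd.DatetimeIndex(["2020-02-28", "2020-02-29"]))
    assert float(thr.isel(time=0).values.squeeze()) == float(
        thr.isel(time=1).values.squeeze()
    )


def test_exceedance_strict_and_missing():
    times = pd.date_range("2001-01-01", "2002-12-31", freq="D")
    cube = make_cube(np.full((len(times), 1, 2), 2.0), times=times)
    clim = calendar_percentile(cube, q=0.9, window=15)
    # cube equal to its (constant) thresholds: strict comparison, all False
    assert not exceedance_mask(cube, clim, "above").any()
    assert not exceedance_mask(cube, clim, "below").any()

    bumped = cube.copy(deep=True)
    bumped.values[10, 0, 1] = 3.0
    mask = exceedance_mask(bumped, clim, "above")
    assert int(mask.sum()) == 1 and bool(mask.values[10, 0, 1])

    withnan = cube.copy(deep=True)
    withnan.values[5, 0, 0] = np.nan
    mask = exceedance_mask(withnan, clim, "above")
    assert not bool(mask.values[5, 0, 0])
    assert bool(mask["missing"].values[5, 0, 0])

    with pytest.raises(ValueError):
        exceedance_mask(cube, clim, "sideways")


@pytest.mark.parametrize(
    "flags, expected",
    [
        ([False, True, True, True, False, True], 3),
        ([True] * 4, 4),
        ([False, False], 0),
    ],
)
def test_longest_run_small_cases(flags, expected):
    series = pd.Series(flags, index=pd.date_range("2019-01-01", periods=len(flags)))
    assert longest_run(series).duration == expected


def test_longest_run_reported_event_windows():
    """The Gulf-average chill exceedance of 30 Jan-7 Feb 2019 is a 9-day run;
    the rainfall exceedance of 29 Jan-7 Feb is 10 days."""
    times = pd.date_range("2019-01-01", "2019-02-28", freq="D")
    chill_mask = pd.Series(times.isin(pd.date_range("2019-01-30", "2019-02-07")), index=times)
    summary = longest_run(chill_mask)
    assert summary.duration == 9
    assert summary.onset == pd.Timestamp("2019-01-30")
    assert summary.offset == pd.Timestamp("2019-02-07")

    rain_mask = pd.Series(times.isin(pd.date_range("2019-01-29", "2019-02-07")), index=times)
    assert longest_run(rain_mask).duration == 10


def test_longest_run_matches_brute_force_scan():
    rng = np.random.default_rng(99)
    for _ in range(1000):
        n = int(rng.integers(1, 40))
        flags = rng.random(n) < 0.5
        series = pd.Series(flags, index=pd.date_range("2019-01-01", periods=n))
        # brute force: longest all-True window
        best = max(
            (j - i for i in range(n) for j in range(i, n + 1) if flags[i:j].all()),
            default=0,
        )
        assert longest_run(series).duration == best


def test_longest_run_peak_and_gap_rejection():
    times = pd.date_range("2019-01-01", periods=5)
    series = pd.Series([False, True, True, True, False], index=times)
    values = pd.Series([0.0, 5.0, 9.0, 7.0, 0.0], index=times)
    summary = longest_run(series, values)
    assert summary.peak_value == 9.0
    assert summary.peak_date == pd.Timestamp("2019-01-03")
    assert summary.duration == summary.offset.dayofyear - summary.onset.dayofyear + 1

    gappy = series.drop(times[2])
    with pytest.raises(ValueError, match="daily"):
        longest_run(gappy)


def test_area_average_weighting():
    times = pd.date_range("2019-01-01", periods=2)
    uniform = make_cube(np.full((2, 3, 3), 4.0), times=times,
                        lat=np.array([-22.0, -20.0, -18.5]),
                        lon=np.array([138.0, 140.0, 144.0]))
    np.testing.assert_allclose(area_average(uniform, GULF_REGION).values, 4.0)

    single = area_average(uniform, RegionBox(139.9, 140.1, -20.1, -19.9))
    np.testing.assert_allclose(single.values, uniform.sel(lat=-20.0, lon=140.0).values)

    # two cells at different latitudes: hand-computed cosine weights
    two = make_cube(np.array([[[1.0], [3.0]]]), times=times[:1],
                    lat=np.array([-22.0, -18.5]), lon=np.array([140.0]))
    w1, w2 = np.cos(np.deg2rad(-22.0)), np.cos(np.deg2rad(-18.5))
    expected = (1.0 * w1 + 3.0 * w2) / (w1 + w2)
    np.testing.assert_allclose(area_average(two, GULF_REGION).values, [expected])

    with pytest.raises(ValueError, match="region"):
        area_average(uniform, RegionBox(10.0, 20.0, 30.0, 40.0))


def test_area_fraction_exceeding():
    times = pd.date_range("2019-01-01", periods=1)
    lat = np.array([-20.0, -20.0 + 1e-9])  # equal-latitude pair
    lon = np.array([140.0, 141.0])
    all_true = make_cube(np.ones((1, 2, 2), dtype=bool), times=times, lat=lat, lon=lon)
    assert float(area_fraction_exceeding(all_true, GULF_REGION).values.squeeze()) == 1.0
    all_false = make_cube(np.zeros((1, 2, 2), dtype=bool), times=times, lat=lat, lon=lon)
    assert float(area_fraction_exceeding(all_false, GULF_REGION).values.squeeze()) == 0.0
    half = make_cube(np.array([[[True, True], [False, False]]]), times=times, lat=lat, lon=lon)
    assert float(area_fraction_exceeding(half, GULF_REGION).values.squeeze()) == pytest.approx(0.5)
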