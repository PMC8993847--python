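"""RMM phase geometry, stall residence, member subsets and MSLP composites."""

import numpy as np
import pandas as pd
import pytest
import xarray as xr

from chillcast import (
    CompositeConfig,
    StallCriteria,
    amplitude_phase,
    anomaly_vs_smoothed_clim,
    classify_members,
    residence_time,
    rmm_series,
    weighted_composite,
)
from chillcast.mjo import read_rmm, write_rmm

from conftest import make_cube


@pytest.mark.parametrize(
    "rmm1, rmm2, amp, phase",
    [
        (1.5, 0.0, 1.5, 5),  # angle 0
        (0.3, 0.9, 0.9486832980505138, 6),  # angle ~71.6
        (-1.0, -1.0, np.sqrt(2.0), 2),  # angle 225: closed-left boundary
        (-1.2, 0.0, 1.2, 1),  # angle 180
        (0.0, -1.3, 1.3, 3),  # angle 270
    ],
)
def test_amplitude_phase_examples(rmm1, rmm2, amp, phase):
    a, p = amplitude_phase(rmm1, rmm2)
    assert a == pytest.approx(amp)
    assert p == phase


def test_amplitude_phase_octant_centers_round_trip():
    """Each octant center angle maps back to its own phase."""
    for phase in range(1, 9):
        angle = np.deg2rad(180.0 + 45.0 * (phase - 1) + 22.5)
        a, p = amplitude_phase(1.3 * np.cos(angle), 1.3 * np.sin(angle))
        assert p == phase and a == pytest.approx(1.3)


def test_zero_vector_flagged_undefined():
    a, p = amplitude_phase(0.0, 0.0)
    assert a == 0.0 and p == 0


def _series_from_phases(phases, active):
    """Build an RMM table realizing given phases (octant centers) and activity."""
    phases = np.asarray(phases)
    amp = np.where(np.asarray(active), 1.5, 0.5)
    angle = np.deg2rad(180.0 + 45.0 * (phases - 1) + 22.5)
    dates = pd.date_range("2019-01-01", periods=len(phases))
    return rmm_series(dates, amp * np.cos(angle), amp * np.sin(angle))


def brute_residence(phases, active, phase_set, require_active, max_gap):
    n = len(phases)
    ok = [p in phase_set and (a or not require_active) for p, a in zip(phases, active)]
    best = 0
    for i in range(n):
        for j in range(i, n):
            if not (ok[i] and ok[j]):
                continue
            gap, worst = 0, 0
            for k in range(i, j + 1):
                gap = 0 if ok[k] else gap + 1
                worst = max(worst, gap)
            if worst <= max_gap:
                best = max(best, j - i + 1)
    return best


def test_residence_alternation_within_set():
    series = _series_from_phases([5, 6, 6, 7, 7, 7, 6, 8], [True] * 8)
    assert residence_time(series) == 6  # 6<->7 shifts do not break the run


def test_residence_requires_active():
    series = _series_from_phases([6] * 10, [False] * 10)
    assert residence_time(series) == 0
    relaxed = StallCriteria(require_active=False)
    assert residence_time(series, relaxed) == 10


def test_residence_gap_bridging():
    phases = [6, 6, 8, 6, 6, 6]
    series = _series_from_phases(phases, [True] * 6)
    assert residence_time(series) == 3
    bridged = StallCriteria(max_gap_days=1)
    assert residence_time(series, bridged) == 6  # one-day excursion bridged

    with pytest.raises(ValueError):
        residence_time(series.iloc[0:0])


def test_residence_matches_brute_force():
    rng = np.random.default_rng(21)
    for trial in range(1000):
        n = int(rng.integers(1, 25))
        phases = rng.integers(1, 9, n)
        active = rng.random(n) < 0.7
        max_gap = int(rng.integers(0, 3))
        crit = StallCriteria(max_gap_days=max_gap)
        series = _series_from_phases(phases, active)
        expected = brute_residence(phases, active, {6, 7}, True, max_gap)
        assert residence_time(series, crit) == expected, (phases, active, max_gap)


def test_classify_members_partitions():
    crit = StallCriteria()  # >=17 stalled, <13 fast
    members = {}
    for i, days in enumerate([18, 17, 12, 5, 15, 13, 16]):
        phases = [6] * days + [1] * (30 - days)
        members[("m", i)] = _series_from_phases(phases, [True] * 30)
    table = classify_members(members, crit)
    by_res = dict(zip(table["residence_days"], table["category"]))
    assert by_res[18] == "stalled" and by_res[17] == "stalled"
    assert by_res[12] == "fast" and by_res[5] == "fast"
    assert by_res[15] == "neither" and by_res[13] == "neither" and by_res[16] == "neither"
    # the two subsets can never overlap
    assert set(table["category"]) <= {"stalled", "fast", "neither"}
    assert len(table) == 7


def test_stall_criteria_validation():
    with pytest.raises(ValueError):
        StallCriteria(stall_min_days=10, fast_max_days=12)
    with pytest.raises(ValueError):
        StallCriteria(phase_set=frozenset({0, 6}))


def test_rmm_text_round_trip(tmp_path):
    series = _series_from_phases([5, 6, 7], [True, True, False])
    path = tmp_path / "rmm.csv"
    write_rmm(series, path)
    back = read_rmm(path)
    np.testing.assert_allclose(back["rmm1"].values, series["rmm1"].values)
    np.testing.assert_array_equal(back["phase"].values, series["phase"].values)


def test_anomaly_zero_for_constant_climatology():
    times = pd.date_range("2001-01-01", "2002-12-31", freq="D")
    clim_source = make_cube(np.full((len(times), 1, 1), 1013.0), times=times, units="hPa")
    field = make_cube(np.full((10, 1, 1), 1013.0),
                      times=pd.date_range("2019-02-01", periods=10), units="hPa")
    anom = anomaly_vs_smoothed_clim(field, clim_source, 11)
    np.testing.assert_allclose(anom.values, 0.0, atol=1e-10)
    with pytest.raises(ValueError, match="odd"):
        anomaly_vs_smoothed_clim(field, clim_source, 10)


def test_anomaly_smoothing_nearly_transparent_for_annual_cycle():
    """An 11-day boxcar barely attenuates a period-365 sinusoid, so anomalies
    of the cycle itself stay within the closed-form attenuation error."""
    times = pd.date_range("2001-01-01", "2004-12-31", freq="D")
    doy = pd.DatetimeIndex(times).dayofyear.to_numpy()
    cycle = 8.0 * np.sin(2 * np.pi * doy / 365.0)
    clim_source = make_cube(cycle[:, None, None], times=times, units="hPa")
    field = clim_source.sel(time=slice("2003-01-01", "2003-12-31"))
    anom = anomaly_vs_smoothed_clim(field, clim_source, 11)
    # boxcar attenuation of a sinusoid: sin(N pi/P) / (N sin(pi/P))
    atten = np.sin(11 * np.pi / 365) / (11 * np.sin(np.pi / 365))
    bound = 8.0 * (1 - atten) + 0.05
    assert float(np.abs(anom).max()) <= bound


def test_anomaly_mean_zero_on_stationary_run():
    rng = np.random.default_rng(5)
    times = pd.date_range("2001-01-01", "2010-12-31", freq="D")
    data = make_cube(rng.normal(0, 1, size=(len(times), 1, 1)), times=times, units="hPa")
    anom = anomaly_vs_smoothed_clim(data, data, 11)
    assert abs(float(anom.mean())) < 0.02


def _model_cube(value, n_members, times):
    arr = np.full((n_members, len(times), 1, 1), float(value))
    base = make_cube(arr[0], times=times, units="hPa")
    return xr.DataArray(
        arr,
        dims=("member",) + base.dims,
        coords={"member": np.arange(n_members), **{d: base[d] for d in base.dims}},
    )


def test_weighted_composite_equal_model_weight():
    times = pd.date_range("2019-02-01", "2019-02-10", freq="D")
    fields = {"A": _model_cube(4.0, 10, times), "B": _model_cube(-2.0, 1, times)}
    subset = pd.DataFrame(
        {
            "member": [("A", m) for m in range(10)] + [("B", 0)],
            "residence_days": [20] * 11,
            "category": ["stalled"] * 11,
        }
    )
    comp = weighted_composite(fields, subset, "stalled")
    # equal weight per model: (4 + (-2)) / 2, not (10*4 - 2) / 11
    np.testing.assert_allclose(comp.values, 1.0)
    assert comp.attrs["n_models"] == 2

    single = weighted_composite({"A": fields["A"]}, subset, "stalled")
    np.testing.assert_allclose(single.values, 4.0)

    with pytest.raises(ValueError, match="subset"):
        weighted_composite(fields, subset, "fast")


def test_composite_of_full_subset_equals_ensemble_mean():
    rng = np.random.default_rng(9)
    times = pd.date_range("2019-02-01", "2019-02-10", freq="D")
    cube = _model_cube(0.0, 5, times) + rng.normal(size=(5, len(times), 1, 1))
    subset = pd.DataFrame(
        {
            "member": [("A", m) for m in range(5)],
            "residence_days": [20] * 5,
            "category": ["stalled"] * 5,
        }
    )
    cfg = CompositeConfig(window_start="2019-02-02", window_end="2019-02-06")
    comp = weighted_composite({"A": cube}, subset, "stalled", cfg)
    expected = cube.mean("member").sel(time=slice("2019-02-02", "2019-02-06")).mean("time")
    np.testing.assert_allclose(comp.values, expected.values)
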