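"""Daily degree-day methods and seasonal accumulation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from phenocast.degree_days import (
    DegreeDayParams,
    accumulate_gdd,
    daily_dd,
    daily_dd_simple_average,
    daily_dd_single_sine,
    daily_dd_single_triangle,
)

from conftest import diurnal_integral

ALL_METHODS = [
    (daily_dd_simple_average, "flat"),
    (daily_dd_single_triangle, "triangle"),
    (daily_dd_single_sine, "sine"),
]


@pytest.mark.parametrize(
    "fn,tmin,tmax,ldt,expected",
    [
        (daily_dd_simple_average, 15, 25, 9.8, 10.2),
        (daily_dd_simple_average, 2, 8, 9.8, 0.0),
        (daily_dd_simple_average, 5, 25, 9.8, 5.2),
        (daily_dd_single_triangle, 15, 25, 9.8, 10.2),
        (daily_dd_single_triangle, 2, 8, 9.8, 0.0),
        (daily_dd_single_triangle, 5, 25, 9.8, 5.776),   # (25-9.8)^2 / (2*20)
        (daily_dd_single_sine, 15, 25, 9.8, 10.2),
        (daily_dd_single_sine, 2, 8, 9.8, 0.0),
    ],
)
def test_daily_dd_known_values(fn, tmin, tmax, ldt, expected):
    assert fn(tmin, tmax, ldt) == pytest.approx(expected, abs=1e-9)


def test_sine_partial_day_matches_numeric_integration():
    """Threshold between tmin and tmax: the closed form equals the integral
    of the sinusoidal trace above the threshold (~6.224 DD for 5/25/9.8)."""
    oracle = diurnal_integral(5, 25, 9.8, "sine")
    assert daily_dd_single_sine(5, 25, 9.8) == pytest.approx(oracle, abs=1e-6)
    assert oracle == pytest.approx(6.224, abs=1e-3)


@pytest.mark.parametrize("fn", [f for f, _ in ALL_METHODS])
def test_invalid_temperature_order_rejected(fn):
    with pytest.raises(ValueError, match="tmin > tmax"):
        fn(10.0, 5.0, 9.8)


@given(
    tmin=st.floats(-10, 30),
    spread=st.floats(0, 20),
    ldt=st.floats(-5, 35),
)
def test_methods_agree_below_tmin_and_vanish_above_tmax(tmin, spread, ldt):
    tmax = tmin + spread
    vals = [fn(tmin, tmax, ldt) for fn, _ in ALL_METHODS]
    if ldt <= tmin:
        assert all(v == pytest.approx((tmin + tmax) / 2 - ldt, abs=1e-12) for v in vals)
    if ldt >= tmax:
        assert all(v == 0.0 for v in vals)
    assert all(v >= 0.0 for v in vals)


@given(
    tmin=st.floats(-10, 25),
    spread=st.floats(0.5, 20),
    ldt=st.floats(0, 20),
    bump=st.floats(0.1, 5),
)
def test_daily_dd_non_increasing_in_threshold(tmin, spread, ldt, bump):
    tmax = tmin + spread
    for fn, _ in ALL_METHODS:
        assert fn(tmin, tmax, ldt + bump) <= fn(tmin, tmax, ldt) + 1e-12


def test_methods_match_integration_on_random_triples():
    """Each closed form equals trapezoid integration of its diurnal curve."""
    rng = np.random.default_rng(42)
    for _ in range(50):
        tmin = rng.uniform(-5, 25)
        tmax = tmin + rng.uniform(0.1, 20)
        ldt = rng.uniform(0, 20)
        for fn, curve in ALL_METHODS:
            assert fn(tmin, tmax, ldt) == pytest.approx(
                diurnal_integral(tmin, tmax, ldt, curve), abs=1e-6
            )


def test_upper_threshold_horizontal_cutoff():
    """With a UDT the day contributes the area between LDT and min(curve, UDT)."""
    tmin, tmax, ldt, udt = 10.0, 30.0, 12.0, 25.0
    params = DegreeDayParams(method="single_sine", ldt=ldt, udt=udt, start_doy=1)
    tau = np.linspace(0, 1, 100_001)
    temp = (tmin + tmax) / 2 + (tmax - tmin) / 2 * np.sin(2 * np.pi * tau)
    oracle = np.trapezoid(np.clip(temp, ldt, udt) - ldt, tau)
    assert daily_dd(tmin, tmax, params) == pytest.approx(oracle, abs=1e-6)
    with pytest.raises(ValueError, match="ldt.*udt"):
        DegreeDayParams(ldt=20.0, udt=15.0)


class TestAccumulateGdd:
    def test_constant_series_cumulates_linearly(self, constant_weather):
        params = DegreeDayParams(method="simple_average", ldt=9.8, start_doy=1)
        out = accumulate_gdd(constant_weather, params)
        assert out["cumulative_gdd"].iloc[-1] == pytest.approx(102.0)
        assert np.all(np.diff(out["cumulative_gdd"]) >= 0)

    def test_start_after_series_end_gives_zero(self, constant_weather):
        params = DegreeDayParams(method="simple_average", ldt=9.8, start_doy=366)
        out = accumulate_gdd(constant_weather, params)
        assert (out["daily_dd"] == 0).all()
        assert (out["cumulative_gdd"] == 0).all()

    def test_zero_before_start_doy(self, constant_weather):
        # series starts 1 May (DOY 121); accumulation from DOY 125
        params = DegreeDayParams(method="simple_average", ldt=9.8, start_doy=125)
        out = accumulate_gdd(constant_weather, params)
        doy = pd.to_datetime(out["date"]).dt.dayofyear
        assert (out.loc[doy < 125, "daily_dd"] == 0).all()
        assert (out.loc[doy >= 125, "daily_dd"] == 10.2).all()

    def test_random_series_matches_per_day_oracle(self):
        rng = np.random.default_rng(7)
        dates = pd.date_range("2020-03-01", periods=60, freq="D")
        tmin = rng.uniform(-2, 15, len(dates))
        tmax = tmin + rng.uniform(0, 15, len(dates))
        weather = pd.DataFrame(
            {"site_year_id": "SY", "date": dates, "tmin_c": tmin, "tmax_c": tmax}
        )
        params = DegreeDayParams(method="single_sine", ldt=9.8, start_doy=70)
        out = accumulate_gdd(weather, params)
        doy = dates.dayofyear.to_numpy()
        expected = np.cumsum(
            [
                daily_dd_single_sine(lo, hi, 9.8) if d >= 70 else 0.0
                for lo, hi, d in zip(tmin, tmax, doy)
            ]
        )
        np.testing.assert_allclose(out["cumulative_gdd"].to_numpy(), expected, atol=1e-10)

    def test_missing_day_raises_gap_error(self, constant_weather):
        gappy = constant_weather.drop(index=4)
        with pytest.raises(ValueError, match="gap"):
            accumulate_gdd(gappy, DegreeDayParams(ldt=9.8, start_doy=1))

    def test_duplicate_date_rejected(self, constant_weather):
        dup = pd.concat([constant_weather, constant_weather.iloc[[3]]])
        with pytest.raises(ValueError, match="duplicate"):
            accumulate_gdd(dup, DegreeDayParams(ldt=9.8, start_doy=1))

    def test_empty_series_gives_empty_output(self):
        empty = pd.DataFrame(columns=["site_year_id", "date", "tmin_c", "tmax_c"])
        out = accumulate_gdd(empty, DegreeDayParams())
        assert len(out) == 0

    def test_leap_year_uses_calendar_doy(self):
        # 2020 is a leap year: 1 March is DOY 61, not 60
        dates = pd.date_range("2020-02-28", periods=4, freq="D")
        weather = pd.DataFrame(
            {"site_year_id": "SY", "date": dates, "tmin_c": 15.0, "tmax_c": 25.0}
        )
        out = accumulate_gdd(weather, DegreeDayParams(method="simple_average", ldt=9.8, start_doy=61))
        expected = [0.0, 0.0, 10.2, 10.2]  # 28 Feb (59), 29 Feb (60), 1 Mar (61), 2 Mar (62)
        np.testing.assert_allclose(out["daily_dd"], expected)
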