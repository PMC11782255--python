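"""Synthetic weather, trap-count and rearing generators."""

import numpy as np
import pandas as pd
import pytest

from phenocast.flight_model import logistic_curve
from phenocast.synthetic_data import (
    SimConfig,
    gen_cumulative_catch,
    gen_dev_times,
    gen_trap_counts,
    gen_weather,
)


class TestGenWeather:
    def test_zero_noise_flat_cycle_is_constant(self):
        config = SimConfig(seed=0, n_site_years=2, n_years=1, annual_mean_c=20.0,
                           annual_amplitude_c=0.0, daily_noise_sd_c=0.0, anomaly_sd_c=0.0,
                           diurnal_range_c=10.0)
        w = gen_weather(config)
        assert (w["tmin_c"] == 15.0).all()
        assert (w["tmax_c"] == 25.0).all()

    def test_same_seed_is_bit_reproducible(self):
        config = SimConfig(seed=9, n_site_years=3, n_years=2)
        pd.testing.assert_frame_equal(gen_weather(config), gen_weather(config))

    def test_annual_amplitude_sets_seasonal_swing(self):
        """Warmest minus coldest monthly mean recovers ~2x the amplitude of
        the generating sinusoid (recomputed from the noiseless cycle)."""
        config = SimConfig(seed=2, n_site_years=1, n_years=1,
                           annual_amplitude_c=12.0, daily_noise_sd_c=0.0, anomaly_sd_c=0.0)
        w = gen_weather(config)
        mid = (w["tmin_c"] + w["tmax_c"]) / 2
        monthly = mid.groupby(w["date"].dt.month).mean()
        doy = w["date"].dt.dayofyear.to_numpy()
        cycle = config.annual_mean_c + 12.0 * np.cos(2 * np.pi * (doy - 196) / 365.25)
        expected = pd.Series(cycle).groupby(w["date"].dt.month.to_numpy()).mean()
        swing = monthly.max() - monthly.min()
        assert swing == pytest.approx(expected.max() - expected.min(), abs=1e-9)
        assert swing == pytest.approx(24.0, abs=1.0)

    def test_tmin_never_exceeds_tmax(self):
        w = gen_weather(SimConfig(seed=3, n_site_years=4, n_years=2))
        assert (w["tmin_c"] <= w["tmax_c"]).all()


@pytest.fixture(scope="module")
def config_weather():
    config = SimConfig(seed=17, n_site_years=10, n_years=5)
    return config, gen_weather(config)


class TestGenTrapCounts:
    def test_same_seed_identical_counts(self, config_weather):
        config, weather = config_weather
        pd.testing.assert_frame_equal(
            gen_trap_counts(config, weather), gen_trap_counts(config, weather)
        )

    def test_seasonal_totals_pass_filter(self, config_weather):
        config, weather = config_weather
        traps = gen_trap_counts(config, weather)
        assert (traps.groupby("site_year_id")["count"].sum() > 20).all()

    def test_cumulative_proportions_monotone_and_terminal(self, config_weather):
        config, weather = config_weather
        traps = gen_trap_counts(config, weather)
        for _, grp in traps.groupby("site_year_id"):
            cum = grp["count"].cumsum() / grp["count"].sum()
            assert (cum.diff().dropna() >= 0).all()
            assert cum.iloc[-1] == 1.0

    def test_noise_free_counts_track_the_logistic(self):
        config = SimConfig(seed=18, n_site_years=4, n_years=2, flight_sigma=0.0,
                           expected_seasonal_total=5000.0)
        weather = gen_weather(config)
        traps = gen_trap_counts(config, weather)
        # Poisson realisation only: cumulative proportions close to the curve
        from phenocast.degree_days import DegreeDayParams, accumulate_gdd
        from phenocast.flight_model import cumulative_catch

        gdd = accumulate_gdd(weather, DegreeDayParams(method=config.dd_method,
                                                      ldt=config.ldt, start_doy=config.start_doy))
        catch = cumulative_catch(traps.drop(columns=["plateau_warning"]), gdd)
        expected = logistic_curve(catch["gdd"].to_numpy(), config.flight_a,
                                  config.flight_b, config.flight_c)
        assert np.max(np.abs(catch["cum_prop"].to_numpy() - expected)) < 0.05


class TestGenCumulativeCatch:
    def test_sigma_zero_lies_exactly_on_logistic(self):
        config = SimConfig(seed=19, n_site_years=5, n_years=5, flight_sigma=0.0)
        weather = gen_weather(config)
        data = gen_cumulative_catch(config, weather)
        expected = logistic_curve(data["gdd"].to_numpy(), 1.0, 270.0, 30.0)
        np.testing.assert_allclose(data["cum_prop"].to_numpy(), expected, atol=1e-12)

    def test_noise_scales_with_variance_covariate(self):
        config = SimConfig(seed=20, n_site_years=200, n_years=2,
                           flight_sigma=0.05, flight_delta=1.0)
        weather = gen_weather(config)
        data = gen_cumulative_catch(config, weather)
        resid = data["cum_prop"] - logistic_curve(data["gdd"], 1.0, 270.0, 30.0)
        sd_by_year = resid.groupby(data["year"]).std()
        # delta = 1 with year indices 1 and 2: second year has ~2x the spread
        assert sd_by_year.iloc[1] / sd_by_year.iloc[0] == pytest.approx(2.0, rel=0.25)


class TestGenDevTimes:
    def test_noiseless_closed_form_days(self):
        config = SimConfig(seed=0, rate_noise_cv=0.0, dev_k={"egg_to_adult": 650.0},
                           temperatures=(22.0,), failure_temperatures=())
        dev = gen_dev_times(config)
        assert dev["days"].unique() == pytest.approx([650.0 / 12.2])

    def test_below_threshold_fails(self):
        config = SimConfig(seed=0, dev_k={"larva": 650.0}, temperatures=(9.0, 22.0),
                           failure_temperatures=())
        dev = gen_dev_times(config)
        assert not dev.loc[dev["temperature_c"] == 9.0, "completed"].any()
        assert dev.loc[dev["temperature_c"] == 22.0, "completed"].all()

    def test_designated_failure_temperature(self):
        dev = gen_dev_times(SimConfig(seed=4))
        assert not dev.loc[dev["temperature_c"] == 12.0, "completed"].any()
        assert dev.loc[dev["temperature_c"] == 17.0, "completed"].all()

    def test_same_seed_identical(self):
        config = SimConfig(seed=6)
        pd.testing.assert_frame_equal(gen_dev_times(config), gen_dev_times(config))

    def test_durations_positive_and_finite(self):
        dev = gen_dev_times(SimConfig(seed=7, rate_noise_cv=0.5))
        done = dev[dev["completed"]]
        assert (done["days"] > 0).all()
        assert np.isfinite(done["days"]).all()
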