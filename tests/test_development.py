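"""Rate regression, threshold/thermal-constant estimation, fixed-LDT requirements."""

import numpy as np
import pandas as pd
import pytest

from phenocast.development import (
    fit_all_stages,
    fit_stage_rate,
    fixed_ldt_table,
    pooled_ldt,
    thermal_constant_fixed_ldt,
)
from phenocast.synthetic_data import SimConfig, gen_dev_times


def make_obs(temps, days, stage="larva", diet="artificial", completed=True):
    temps = np.asarray(temps, dtype=float)
    return pd.DataFrame(
        {
            "specimen_id": [f"s{i}" for i in range(len(temps))],
            "temperature_c": temps,
            "diet": diet,
            "stage": stage,
            "days": days,
            "completed": completed,
        }
    )


def linear_rate_obs(t=9.8, k=650.0, temps=(17, 22, 27, 32), reps=5):
    T = np.repeat(temps, reps).astype(float)
    rates = (T - t) / k
    return make_obs(T, 1.0 / rates)


class TestFitStageRate:
    def test_noiseless_data_recovers_t_and_k_exactly(self):
        est = fit_stage_rate(linear_rate_obs())
        assert est.t == pytest.approx(9.8, abs=1e-9)
        assert est.k == pytest.approx(650.0, abs=1e-6)
        assert est.se_t == pytest.approx(0.0, abs=1e-6)
        assert est.se_k == pytest.approx(0.0, abs=1e-3)
        assert est.status == "ok"

    def test_threshold_and_constant_are_algebraic_in_coefficients(self):
        # y = a + b*T with a = -0.0150769, b = 0.0015385
        a, b = -0.0150769, 0.0015385
        T = np.array([15.0, 20.0, 25.0, 30.0])
        est = fit_stage_rate(make_obs(T, 1.0 / (a + b * T)))
        assert est.t == pytest.approx(-a / b, rel=1e-9)
        assert est.k == pytest.approx(1.0 / b, rel=1e-9)
        assert est.t == pytest.approx(9.8, abs=0.01)
        assert est.k == pytest.approx(650.0, abs=0.05)

    def test_standard_errors_match_bootstrap(self):
        """Delta-method SEs agree with a nonparametric bootstrap under
        homoskedastic Gaussian rate noise (moderate resample count here;
        the full 10k-resample check runs in the acceptance suite)."""
        rng = np.random.default_rng(11)
        T = np.repeat([17.0, 22.0, 27.0, 32.0], 20)
        rates = (T - 9.8) / 650.0 + rng.normal(0, 0.003, len(T))
        obs = make_obs(T, 1.0 / rates)
        est = fit_stage_rate(obs)
        boots_t, boots_k = [], []
        for _ in range(1000):
            idx = rng.integers(0, len(T), len(T))
            e = fit_stage_rate(obs.iloc[idx].reset_index(drop=True))
            boots_t.append(e.t)
            boots_k.append(e.k)
        assert est.se_t == pytest.approx(np.std(boots_t, ddof=1), rel=0.25)
        assert est.se_k == pytest.approx(np.std(boots_k, ddof=1), rel=0.25)

    def test_single_temperature_is_rank_deficient(self):
        with pytest.raises(ValueError, match="distinct"):
            fit_stage_rate(make_obs([22.0, 22.0, 22.0], [50.0, 52.0, 51.0]))

    def test_negative_slope_flagged_not_silently_accepted(self):
        # rates decreasing with temperature: non-physical
        est = fit_stage_rate(make_obs([17.0, 22.0, 27.0], [10.0, 20.0, 40.0]))
        assert est.status == "non_physical"
        assert np.isnan(est.t) and np.isnan(est.k)

    def test_complete_mortality_temperature_excluded(self):
        obs = linear_rate_obs()
        dead = make_obs([12.0] * 5, np.nan, completed=False)
        est = fit_stage_rate(pd.concat([obs, dead], ignore_index=True))
        assert est.excluded_temperatures == (12.0,)
        assert est.t == pytest.approx(9.8, abs=1e-9)

    def test_rate_scaling_moves_k_not_t(self):
        """Scaling all rates by c scales k by 1/c and leaves t unchanged."""
        obs = linear_rate_obs()
        scaled = obs.assign(days=obs["days"] / 3.0)  # rates x3
        est, est3 = fit_stage_rate(obs), fit_stage_rate(scaled)
        assert est3.t == pytest.approx(est.t, abs=1e-9)
        assert est3.k == pytest.approx(est.k / 3.0, rel=1e-9)


class TestPooledLdt:
    def test_single_value(self):
        assert pooled_ldt([9.8]) == (9.8, 0.0)

    def test_arithmetic_mean(self):
        mean, se = pooled_ldt([8.0, 11.6])
        assert mean == pytest.approx(9.8)
        assert se == pytest.approx(np.std([8.0, 11.6], ddof=1) / np.sqrt(2))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pooled_ldt([])

    def test_simulated_stage_thresholds_pool_near_truth(self):
        rng = np.random.default_rng(5)
        ts = rng.normal(9.8, 0.8, size=9)
        mean, se = pooled_ldt(list(ts))
        assert abs(mean - 9.8) < 2 * se + 1e-12


class TestFixedLdtRequirement:
    def test_single_specimen_arithmetic(self):
        req = thermal_constant_fixed_ldt(make_obs([22.0], [30.5]), ldt=9.8)
        assert req.k_dd == pytest.approx(30.5 * 12.2)

    def test_mean_and_se_of_two_specimens(self):
        # per-specimen degree days 370 and 374
        obs = make_obs([22.0, 22.0], [370 / 12.2, 374 / 12.2])
        req = thermal_constant_fixed_ldt(obs, ldt=9.8)
        assert req.k_dd == pytest.approx(372.0)
        assert req.se_k_dd == pytest.approx(2.0)

    def test_temperature_at_or_below_ldt_rejected(self):
        with pytest.raises(ValueError, match="at or below"):
            thermal_constant_fixed_ldt(make_obs([9.8], [40.0]), ldt=9.8)

    def test_noiseless_linear_rates_reproduce_k_at_own_threshold(self):
        """At ldt = t on exact linear-rate data, days*(T - t) = k at every T."""
        obs = linear_rate_obs(t=9.8, k=650.0)
        req = thermal_constant_fixed_ldt(obs, ldt=9.8)
        assert req.k_dd == pytest.approx(650.0, rel=1e-12)
        assert req.se_k_dd == pytest.approx(0.0, abs=1e-9)


def test_parameter_recovery_bias_shrinks_with_noise():
    """days = k/(T - t) + noise: (t, k) recovered with bias -> 0 as noise -> 0."""
    rng = np.random.default_rng(3)
    T = np.repeat([17.0, 22.0, 27.0, 32.0], 50)
    biases = []
    for sd in (0.002, 0.0002):
        rates = (T - 9.8) / 650.0 + rng.normal(0, sd, len(T))
        est = fit_stage_rate(make_obs(T, 1.0 / rates))
        biases.append(abs(est.t - 9.8) + abs(est.k - 650.0) / 650.0)
    assert biases[1] < biases[0]
    assert biases[1] < 0.05


def test_generated_rearing_data_end_to_end():
    config = SimConfig(seed=21, dev_k={"egg_to_adult": 648.47}, n_per_temperature=20)
    dev = gen_dev_times(config)
    fits = fit_all_stages(dev)
    combined = [f for f in fits if f.diet == "combined"][0]
    assert combined.excluded_temperatures == (12.0,)
    assert combined.t == pytest.approx(9.8, abs=3 * combined.se_t)
    assert combined.k == pytest.approx(648.47, rel=0.15)
    table = fixed_ldt_table(dev, ldt=9.8)
    row = table[(table.stage == "egg_to_adult") & (table.diet == "combined")].iloc[0]
    assert row.k_dd == pytest.approx(648.47, rel=0.1)
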