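import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=50, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture
def constant_weather():
    """Ten consecutive days of (15, 25) °C for one site-year."""
    dates = pd.date_range("2021-05-01", periods=10, freq="D")
    return pd.DataFrame(
        {"site_year_id": "SY1", "date": dates, "tmin_c": 15.0, "tmax_c": 25.0}
    )


@pytest.fixture
def long_constant_weather():
    """A full season of (15, 25) °C days (10.2 DD/day at LDT 9.8)."""
    dates = pd.date_range("2021-04-01", periods=200, freq="D")
    return pd.DataFrame(
        {"site_year_id": "SY1", "date": dates, "tmin_c": 15.0, "tmax_c": 25.0}
    )


def diurnal_integral(tmin, tmax, ldt, curve, n_steps=100_000):
    """Trapezoid integration of a diurnal temperature curve above a threshold.

    Independent oracle for the closed-form daily degree-day methods.
    ``curve`` is 'sine', 'triangle' or 'flat' (the constant daily mean used
    by the simple-average method).
    """
    tau = np.linspace(0.0, 1.0, n_steps + 1)
    mean = (tmin + tmax) / 2.0
    alpha = (tmax - tmin) / 2.0
    if curve == "sine":
        temp = mean + alpha * np.sin(2 * np.pi * tau)
    elif curve == "triangle":
        temp = tmin + (tmax - tmin) * (2 * np.minimum(tau, 1.0 - tau))
    elif curve == "flat":
        temp = np.full_like(tau, mean)
    else:
        raise ValueError(curve)
    return float(np.trapezoid(np.maximum(temp - ldt, 0.0), tau))
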