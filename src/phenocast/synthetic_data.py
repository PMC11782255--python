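"""Seeded synthetic weather, trap-count and rearing datasets.

The analysis pipeline was built for field and growth-chamber data that are
not bundled with the package, so every stage is exercised against generated
data with the same statistical structure the methods assume:

* daily min/max temperatures from a sinusoidal annual cycle (peak in
  mid-July) with Gaussian day-to-day noise and a fixed diurnal range,
  emulating gridded surface-temperature extractions for a temperate site;
* weekly pheromone-trap counts whose seasonal cumulative proportion follows
  a three-parameter logistic in accumulated GDD, with year-level
  variance-power noise and seasonal totals above the >20-capture filter;
* constant-temperature rearing records with linear development rates above a
  true threshold, Gaussian rate noise, and complete failure at designated
  temperatures (mirroring the observed complete larval mortality at 12 °C).

All generators take a :class:`numpy.random.Generator` or integer seed and
are bit-reproducible for a fixed seed and package version.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .degree_days import DegreeDayParams, accumulate_gdd
from .flight_model import logistic_curve

__all__ = ["SimConfig", "gen_weather", "gen_trap_counts", "gen_cumulative_catch", "gen_dev_times"]


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters for the synthetic generators.

    Defaults emulate the monitored system: a temperate valley climate, a
    flight curve rising through late spring on a DOY-120 / LDT-9.8 single-sine
    GDD axis, weekly trap visits from May through October, and a rearing
    design of five constant temperatures by two diets with 20 specimens per
    cell.
    """

    seed: int = 0

    # --- weather -----------------------------------------------------------
    n_site_years: int = 40
    first_year: int = 2016
    n_years: int = 8
    annual_mean_c: float = 12.0      # valley annual mean temperature
    annual_amplitude_c: float = 8.0  # mid-July peak minus annual mean
    daily_noise_sd_c: float = 2.5
    anomaly_sd_c: float = 1.5        # per-site-year climate anomaly (inter-annual variation)
    diurnal_range_c: float = 12.0

    # --- flight curve ------------------------------------------------------
    flight_a: float = 1.0
    flight_b: float = 270.0          # GDD at half-asymptote
    flight_c: float = 30.0           # growth-rate parameter, GDD
    flight_sigma: float = 0.05
    flight_delta: float = 0.5
    variance_covariate: str = "year_index"  # identifiable scale for |v|^delta
    dd_method: str = "single_sine"
    ldt: float = 9.8
    start_doy: int = 120

    # --- trap sampling -----------------------------------------------------
    season_start_doy: int = 130
    season_end_doy: int = 290
    visit_interval_days: int = 7
    expected_seasonal_total: float = 150.0

    # --- development -------------------------------------------------------
    dev_t: float = 9.8
    dev_k: dict = field(default_factory=lambda: {
        "egg": 75.72, "larva": 372.44, "pupa": 186.67, "egg_to_adult": 648.47,
    })
    rate_noise_cv: float = 0.15      # noise sd as a fraction of the mean rate
    n_per_temperature: int = 20
    temperatures: tuple = (12.0, 17.0, 22.0, 27.0, 32.0)
    failure_temperatures: tuple = (12.0,)
    diets: tuple = ("artificial", "perennial_ryegrass")


def _rng(rng: np.random.Generator | int | None) -> np.random.Generator:
    return rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)


def _site_year_table(config: SimConfig) -> pd.DataFrame:
    """Deterministic assignment of site-years to calendar years (round robin)."""
    years = config.first_year + np.arange(config.n_site_years) % config.n_years
    sites = np.arange(config.n_site_years) // config.n_years + 1
    ids = [f"S{s:02d}_{y}" for s, y in zip(sites, years)]
    return pd.DataFrame({"site_year_id": ids, "year": years})


def gen_weather(config: SimConfig, rng: np.random.Generator | int | None = None) -> pd.DataFrame:
    """Generate daily min/max temperatures for every configured site-year.

    The daily mean follows ``annual_mean + amplitude*cos(2*pi*(doy-196)/365.25)``
    (peak near mid-July) plus a per-site-year climate anomaly
    (N(0, anomaly_sd) — inter-annual variation in how warm a season runs)
    plus day-to-day noise N(0, daily_noise_sd); tmin/tmax sit half the
    diurnal range below/above the mean, so tmin <= tmax always holds.
    Covers the full calendar year.
    """
    rng = _rng(config.seed if rng is None else rng)
    frames = []
    for _, row in _site_year_table(config).iterrows():
        dates = pd.date_range(f"{row.year}-01-01", f"{row.year}-12-31", freq="D")
        doy = dates.dayofyear.to_numpy()
        mean = (
            config.annual_mean_c
            + rng.normal(0.0, config.anomaly_sd_c)
            + config.annual_amplitude_c * np.cos(2 * np.pi * (doy - 196) / 365.25)
            + rng.normal(0.0, config.daily_noise_sd_c, size=len(dates))
        )
        half = config.diurnal_range_c / 2.0
        frames.append(
            pd.DataFrame(
                {
                    "site_year_id": row.site_year_id,
                    "date": dates,
                    "tmin_c": mean - half,
                    "tmax_c": mean + half,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def _visit_schedule(config: SimConfig, year: int) -> pd.DatetimeIndex:
    start = pd.Timestamp(year=year, month=1, day=1) + pd.Timedelta(days=config.season_start_doy - 1)
    end = pd.Timestamp(year=year, month=1, day=1) + pd.Timedelta(days=config.season_end_doy - 1)
    return pd.date_range(start, end, freq=f"{config.visit_interval_days}D")


def _covariate(config: SimConfig, years: np.ndarray) -> np.ndarray:
    if config.variance_covariate == "year_index":
        return years - config.first_year + 1.0
    if config.variance_covariate == "year":
        return years.astype(float)
    raise ValueError(f"unknown variance covariate {config.variance_covariate!r}")


def _expected_curve(config: SimConfig, weather: pd.DataFrame):
    params = DegreeDayParams(method=config.dd_method, ldt=config.ldt, start_doy=config.start_doy)
    gdd = accumulate_gdd(weather, params)
    gdd_by_sy = {sy: grp.set_index("date")["cumulative_gdd"] for sy, grp in gdd.groupby("site_year_id")}
    return gdd_by_sy


def gen_trap_counts(config: SimConfig, weather: pd.DataFrame, rng=None) -> pd.DataFrame:
    """Generate weekly integer trap counts per site-year.

    The expected cumulative proportion at each visit's GDD comes from the
    configured logistic; year-level Gaussian noise with sd
    ``sigma * |v|^delta`` distorts the cumulative curve, which is then made
    monotone, and weekly increments are realised as Poisson counts scaled to
    the expected seasonal total.  Seasonal totals exceed the >20-capture
    filter by construction (totals at or below it are redrawn).  Site-years
    whose season ends before the curve plateaus (expected final proportion
    < 0.99) are flagged in the ``plateau_warning`` column.
    """
    rng = _rng(config.seed + 1 if rng is None else rng)
    gdd_by_sy = _expected_curve(config, weather)
    table = _site_year_table(config)
    v = _covariate(config, table["year"].to_numpy())

    frames = []
    for (_, row), v_i in zip(table.iterrows(), v):
        visits = _visit_schedule(config, row.year)
        x = gdd_by_sy[row.site_year_id].loc[visits].to_numpy(dtype=float)
        p = logistic_curve(x, config.flight_a, config.flight_b, config.flight_c)
        plateau_warning = p[-1] < 0.99 * config.flight_a
        sd = config.flight_sigma * np.abs(v_i) ** config.flight_delta
        for _ in range(1000):
            q = p + rng.normal(0.0, sd, size=len(p)) if sd > 0 else p.copy()
            q = np.clip(np.maximum.accumulate(q), 0.0, 1.0)
            if q[-1] <= 0:
                continue
            q /= q[-1]
            increments = np.diff(np.concatenate([[0.0], q]))
            counts = rng.poisson(config.expected_seasonal_total * increments)
            if counts.sum() > 20:
                break
        else:  # pragma: no cover - astronomically unlikely at default totals
            raise RuntimeError("failed to realise a season with >20 captures")
        frames.append(
            pd.DataFrame(
                {
                    "site_year_id": row.site_year_id,
                    "year": row.year,
                    "visit_date": visits,
                    "count": counts,
                    "plateau_warning": plateau_warning,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def gen_cumulative_catch(config: SimConfig, weather: pd.DataFrame, rng=None) -> pd.DataFrame:
    """Generate cumulative-proportion observations directly from the model.

    Unlike :func:`gen_trap_counts`, which realises integer counts, this
    emits (GDD, cumulative proportion) points carrying exactly the
    regression's error structure — independent Gaussian noise with sd
    ``sigma * |v|^delta`` around the logistic — so parameter-recovery and
    interval-coverage studies see the model they estimate.  With sigma = 0
    the points lie exactly on the curve.  Observations are not forced to be
    monotone or to end at 1.
    """
    rng = _rng(config.seed + 2 if rng is None else rng)
    gdd_by_sy = _expected_curve(config, weather)
    table = _site_year_table(config)
    v = _covariate(config, table["year"].to_numpy())

    frames = []
    for (_, row), v_i in zip(table.iterrows(), v):
        visits = _visit_schedule(config, row.year)
        x = gdd_by_sy[row.site_year_id].loc[visits].to_numpy(dtype=float)
        p = logistic_curve(x, config.flight_a, config.flight_b, config.flight_c)
        sd = config.flight_sigma * np.abs(v_i) ** config.flight_delta
        y = p + rng.normal(0.0, sd, size=len(p)) if sd > 0 else p
        frames.append(
            pd.DataFrame(
                {
                    "site_year_id": row.site_year_id,
                    "year": row.year,
                    "date": visits,
                    "gdd": x,
                    "cum_prop": y,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def gen_dev_times(config: SimConfig, rng=None) -> pd.DataFrame:
    """Generate constant-temperature rearing records for every stage x diet.

    Development rates follow ``(T - t)/k`` plus Gaussian noise with sd equal
    to ``rate_noise_cv`` times the cell's mean rate; days are the reciprocal.
    Non-positive rate draws are redrawn (truncation) so durations stay
    finite.  Temperatures at or below the true threshold, and designated
    failure temperatures, yield ``completed = False`` records with no
    duration.
    """
    rng = _rng(config.seed + 3 if rng is None else rng)
    rows = []
    specimen = 0
    for stage, k in config.dev_k.items():
        for diet in config.diets:
            for T in config.temperatures:
                fails = T <= config.dev_t or T in config.failure_temperatures
                mean_rate = max((T - config.dev_t) / k, 0.0)
                sd = config.rate_noise_cv * mean_rate
                for _ in range(config.n_per_temperature):
                    specimen += 1
                    if fails:
                        rows.append(
                            {"specimen_id": f"sp{specimen:05d}", "temperature_c": T,
                             "diet": diet, "stage": stage, "days": np.nan, "completed": False}
                        )
                        continue
                    rate = rng.normal(mean_rate, sd) if sd > 0 else mean_rate
                    while rate <= 0:
                        rate = rng.normal(mean_rate, sd)
                    rows.append(
                        {"specimen_id": f"sp{specimen:05d}", "temperature_c": T,
                         "diet": diet, "stage": stage, "days": 1.0 / rate, "completed": True}
                    )
    return pd.DataFrame(rows)


def default_config(seed: int = 0, **overrides) -> SimConfig:
    """A :class:`SimConfig` with the stated seed and any field overrides."""
    return replace(SimConfig(seed=seed), **overrides)
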