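"""Daily and accumulated growing degree days (GDD) from daily min/max temperatures.

Three standard horizontal-cutoff calculation methods are provided:

``simple_average``
    DD = max((tmin + tmax)/2 - LDT, 0); the diurnal cycle is ignored.
``single_triangle``
    The day's temperature trace is a symmetric triangle from tmin up to tmax
    and back; DD is the area of that trace above the threshold, normalised to
    one day.
``single_sine``
    The trace is one period of a sine wave between tmin and tmax
    (Baskerville & Emin convention); DD is the area above the threshold.

All methods agree exactly when the threshold lies at or below tmin, and all
return 0 when it lies at or above tmax.  An optional upper developmental
threshold (UDT) is applied as a horizontal cutoff: temperature above the UDT
contributes as if it were equal to the UDT.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "METHODS",
    "DegreeDayParams",
    "daily_dd_simple_average",
    "daily_dd_single_triangle",
    "daily_dd_single_sine",
    "daily_dd",
    "accumulate_gdd",
]

METHODS = ("simple_average", "single_triangle", "single_sine")

#: Accepted aliases for CLI / config convenience.
_METHOD_ALIASES = {
    "average": "simple_average",
    "avg": "simple_average",
    "triangle": "single_triangle",
    "sine": "single_sine",
}


def canonical_method(name: str) -> str:
    """Resolve a method name or alias to one of :data:`METHODS`."""
    name = name.strip().lower()
    name = _METHOD_ALIASES.get(name, name)
    if name not in METHODS:
        raise ValueError(f"unknown degree-day method {name!r}; expected one of {METHODS}")
    return name


@dataclass(frozen=True)
class DegreeDayParams:
    """Parameters governing daily DD calculation and seasonal accumulation.

    Parameters
    ----------
    method:
        One of ``simple_average``, ``single_triangle``, ``single_sine``
        (aliases ``average``/``triangle``/``sine`` accepted).
    ldt:
        Lower developmental threshold in °C.  Development (and hence heat
        accumulation) is assumed to stop below this temperature.
    udt:
        Optional upper developmental threshold in °C (horizontal cutoff).
        The fitted cutworm models use none, so the default is absent.
    start_doy:
        Day of year (1 January = 1) on which accumulation begins, inclusive.
        Daily DD is reported as 0 before this date.
    """

    method: str = "single_sine"
    ldt: float = 9.8
    udt: float | None = None
    start_doy: int = 120

    def __post_init__(self) -> None:
        object.__setattr__(self, "method", canonical_method(self.method))
        if self.udt is not None and not self.ldt < self.udt:
            raise ValueError(f"ldt ({self.ldt}) must be below udt ({self.udt})")
        if not 1 <= int(self.start_doy) <= 366:
            raise ValueError(f"start_doy must be in 1..366, got {self.start_doy}")


def _check_temps(tmin, tmax) -> tuple[np.ndarray, np.ndarray]:
    tmin = np.asarray(tmin, dtype=float)
    tmax = np.asarray(tmax, dtype=float)
    if np.any(tmin > tmax):
        bad = np.flatnonzero(np.atleast_1d(tmin > tmax))
        raise ValueError(f"tmin > tmax at positions {bad.tolist()[:10]}")
    return tmin, tmax


def daily_dd_simple_average(tmin, tmax, ldt: float) -> np.ndarray | float:
    """Degree days from the daily mean temperature, truncated at the threshold.

    The mean is computed first and then truncated (``max(mean - ldt, 0)``);
    sub-threshold temperatures are not substituted before averaging.
    """
    tmin, tmax = _check_temps(tmin, tmax)
    return np.maximum((tmin + tmax) / 2.0 - ldt, 0.0)


def daily_dd_single_triangle(tmin, tmax, ldt: float) -> np.ndarray | float:
    """Degree days as the area of a symmetric triangular diurnal trace above ``ldt``."""
    tmin, tmax = _check_temps(tmin, tmax)
    mean = (tmin + tmax) / 2.0
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        partial = (tmax - ldt) ** 2 / (2.0 * (tmax - tmin))
    out = np.where(ldt <= tmin, mean - ldt, np.where(ldt >= tmax, 0.0, partial))
    return out[()] if out.ndim == 0 else out


def daily_dd_single_sine(tmin, tmax, ldt: float) -> np.ndarray | float:
    """Degree days as the area of a sinusoidal diurnal trace above ``ldt``.

    For tmin < ldt < tmax, with Tm the daily mean and alpha the half-range,
    theta = arcsin((ldt - Tm)/alpha) and

        DD = (1/pi) * [ (Tm - ldt) * (pi/2 - theta) + alpha * cos(theta) ].
    """
    tmin, tmax = _check_temps(tmin, tmax)
    mean = (tmin + tmax) / 2.0
    alpha = (tmax - tmin) / 2.0
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        ratio = np.clip((ldt - mean) / np.where(alpha > 0, alpha, np.nan), -1.0, 1.0)
        theta = np.arcsin(ratio)
        partial = ((mean - ldt) * (np.pi / 2.0 - theta) + alpha * np.cos(theta)) / np.pi
    out = np.where(ldt <= tmin, mean - ldt, np.where(ldt >= tmax, 0.0, partial))
    return out[()] if out.ndim == 0 else out


_DISPATCH = {
    "simple_average": daily_dd_simple_average,
    "single_triangle": daily_dd_single_triangle,
    "single_sine": daily_dd_single_sine,
}


def daily_dd(tmin, tmax, params: DegreeDayParams) -> np.ndarray | float:
    """Daily degree days under ``params.method``, with optional UDT cutoff.

    The horizontal UDT cutoff subtracts the area above the UDT, i.e. the day
    contributes the area between LDT and min(trace, UDT).  For the simple
    average the daily mean is clamped at the UDT.
    """
    fn = _DISPATCH[params.method]
    if params.udt is None:
        return fn(tmin, tmax, params.ldt)
    if params.method == "simple_average":
        tmin_a, tmax_a = _check_temps(tmin, tmax)
        mean = np.minimum((tmin_a + tmax_a) / 2.0, params.udt)
        return np.maximum(mean - params.ldt, 0.0)
    return fn(tmin, tmax, params.ldt) - fn(tmin, tmax, params.udt)


_REQUIRED_WEATHER_COLS = ("site_year_id", "date", "tmin_c", "tmax_c")


def _validate_weather(weather: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in _REQUIRED_WEATHER_COLS if c not in weather.columns]
    if missing:
        raise ValueError(f"weather frame missing columns {missing}")
    weather = weather.copy()
    weather["date"] = pd.to_datetime(weather["date"])
    if np.any(weather["tmin_c"].to_numpy() > weather["tmax_c"].to_numpy()):
        raise ValueError("weather contains rows with tmin_c > tmax_c")
    return weather


def accumulate_gdd(weather: pd.DataFrame, params: DegreeDayParams) -> pd.DataFrame:
    """Accumulate growing degree days per site-year from a daily weather table.

    Parameters
    ----------
    weather:
        Frame with columns ``site_year_id, date, tmin_c, tmax_c``; one row per
        site-year per day.  Dates within a site-year must be strictly
        increasing with no gaps inside the covered window (missing days raise
        rather than being silently interpolated).
    params:
        Method, thresholds and accumulation start day of year.

    Returns
    -------
    DataFrame with columns ``site_year_id, date, daily_dd, cumulative_gdd``.
    Days before ``start_doy`` carry ``daily_dd = 0``.
    """
    weather = _validate_weather(weather)
    if len(weather) == 0:
        return pd.DataFrame(columns=["site_year_id", "date", "daily_dd", "cumulative_gdd"])

    out = []
    for sy, grp in weather.groupby("site_year_id", sort=True):
        grp = grp.sort_values("date")
        dates = grp["date"]
        if dates.duplicated().any():
            raise ValueError(f"duplicate dates in site-year {sy!r}")
        deltas = dates.diff().dropna()
        if (deltas != pd.Timedelta(days=1)).any():
            gap_at = dates[deltas.index][deltas != pd.Timedelta(days=1)].iloc[0]
            raise ValueError(f"gap in weather series for site-year {sy!r} before {gap_at.date()}")
        dd = np.asarray(daily_dd(grp["tmin_c"].to_numpy(), grp["tmax_c"].to_numpy(), params), dtype=float)
        doy = dates.dt.dayofyear.to_numpy()
        dd = np.where(doy >= params.start_doy, dd, 0.0)
        out.append(
            pd.DataFrame(
                {
                    "site_year_id": sy,
                    "date": dates.to_numpy(),
                    "daily_dd": dd,
                    "cumulative_gdd": np.cumsum(dd),
                }
            )
        )
    return pd.concat(out, ignore_index=True)
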