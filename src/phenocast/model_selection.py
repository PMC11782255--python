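"""Biofix grid search and year-split validation of candidate phenology models.

A candidate model is one (degree-day method, accumulation start DOY) pair.
Each candidate is fitted with the heteroskedastic logistic flight-curve model
and scored on the fitting data with MAE, RMSE and the pseudo coefficient of
determination

    R^2 = 1 - sum((y - yhat)^2) / sum((y - ybar)^2),

the conventional fit statistic for nonlinear regressions.  The grid spans
candidate start dates from early January through early May in five-day
steps across the three degree-day methods.  Selected models are validated by
randomly splitting the site-years by calendar year into train and test sets,
fitting on the train years and regressing observed test proportions on their
predictions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .degree_days import METHODS, DegreeDayParams, accumulate_gdd, daily_dd
from .flight_model import FitError, LogisticFit, fit_logistic_gls, predict_cumulative

__all__ = [
    "DEFAULT_DOY_GRID",
    "CandidateModelScore",
    "ValidationReport",
    "pseudo_r2",
    "score_candidate",
    "grid_search_biofix",
    "year_split_cv",
]

logger = logging.getLogger(__name__)

#: Candidate accumulation start dates: DOY 1 through 125 in 5-day steps
#: (25 dates; with the three methods, 75 candidate models).
DEFAULT_DOY_GRID: tuple[int, ...] = tuple(range(1, 126, 5))


@dataclass(frozen=True)
class CandidateModelScore:
    method: str
    start_doy: int
    mae: float
    rmse: float
    pseudo_r2: float
    fit: LogisticFit | None = field(repr=False, default=None)
    error: str | None = None


@dataclass(frozen=True)
class ValidationReport:
    """Observed-vs-predicted validation of one candidate on held-out years."""

    train_years: tuple
    test_years: tuple
    slope: float
    intercept: float
    rmse: float       # RMSE of (observed - predicted) on the test points
    r2: float         # R^2 of the observed-on-predicted linear regression
    mae: float
    pseudo_r2: float  # 1 - SSres/SStot of the raw predictions


def pseudo_r2(y, yhat) -> float:
    """1 - SSres/SStot; 1 for a perfect fit, 0 for the mean-only predictor."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape or y.size < 2:
        raise ValueError("y and yhat must be equal-length vectors of size >= 2")
    sstot = np.sum((y - y.mean()) ** 2)
    if sstot == 0:
        raise ValueError("pseudo R^2 undefined: observations are all identical")
    return float(1.0 - np.sum((y - yhat) ** 2) / sstot)


def score_candidate(
    data: pd.DataFrame, fit: LogisticFit, method: str = "", start_doy: int = 0
) -> CandidateModelScore:
    """MAE, RMSE and pseudo-R^2 of a fitted candidate on its fitting data."""
    y = data["cum_prop"].to_numpy(dtype=float)
    yhat = np.asarray(predict_cumulative(fit, data["gdd"].to_numpy(dtype=float)))
    resid = y - yhat
    return CandidateModelScore(
        method=method,
        start_doy=int(start_doy),
        mae=float(np.mean(np.abs(resid))),
        rmse=float(np.sqrt(np.mean(resid**2))),
        pseudo_r2=pseudo_r2(y, yhat),
        fit=fit,
    )


def _prepare_grid_inputs(traps: pd.DataFrame, weather: pd.DataFrame):
    """Precompute everything that is constant across grid candidates.

    Cumulative proportions and visit dates do not depend on the degree-day
    method or start DOY — only the GDD axis does — so the trap side is
    reduced once to (cum_prop, year, weather-row position) and each
    candidate merely re-derives cumulative degree days and looks them up.
    """
    ww = weather.copy()
    ww["date"] = pd.to_datetime(ww["date"])
    ww = ww.sort_values(["site_year_id", "date"], kind="stable").reset_index(drop=True)
    # validate contiguity once with a throwaway accumulation
    accumulate_gdd(ww, DegreeDayParams(method="simple_average", ldt=0.0, start_doy=1))
    row_of = pd.Series(ww.index, index=pd.MultiIndex.from_frame(ww[["site_year_id", "date"]]))
    group_sizes = ww.groupby("site_year_id", sort=False).size().to_numpy()
    group_starts = np.concatenate([[0], np.cumsum(group_sizes)[:-1]])

    traps = traps.copy()
    traps["visit_date"] = pd.to_datetime(traps["visit_date"])
    parts = []
    for sy, grp in traps.groupby("site_year_id", sort=True):
        grp = grp.sort_values("visit_date")
        total = grp["count"].sum()
        if total <= 20:
            logger.info("dropping site-year %r: seasonal total %d <= 20", sy, total)
            continue
        try:
            pos = row_of.loc[list(zip([sy] * len(grp), grp["visit_date"]))].to_numpy()
        except KeyError as exc:
            raise ValueError(f"visit dates outside weather coverage for site-year {sy!r}") from exc
        parts.append(
            pd.DataFrame(
                {"site_year_id": sy, "year": grp["year"].to_numpy(), "row": pos,
                 "cum_prop": grp["count"].cumsum().to_numpy(dtype=float) / total}
            )
        )
    if not parts:
        raise ValueError("no site-years pass the >20 seasonal-capture filter")
    catch = pd.concat(parts, ignore_index=True)
    doy = ww["date"].dt.dayofyear.to_numpy()
    return ww, doy, group_starts, catch


def grid_search_biofix(
    traps: pd.DataFrame,
    weather: pd.DataFrame,
    ldt: float = 9.8,
    doy_grid: tuple[int, ...] | None = None,
    methods: tuple[str, ...] = METHODS,
    udt: float | None = None,
    **fit_kwargs,
) -> tuple[list[CandidateModelScore], dict[str, CandidateModelScore]]:
    """Fit and score every (method, start DOY) candidate; pick the best per method.

    The best candidate has the lowest MAE; ties break by lower RMSE, then
    earlier start DOY.  A single candidate's fit failure is recorded on its
    score (``error`` set, metrics NaN) rather than aborting the search; only
    if every candidate fails is an error raised.  Extra keyword arguments are
    forwarded to :func:`fit_logistic_gls` (e.g. ``fix_delta=0`` for a plain
    least-squares search, ``variance_covariate="year_index"``).

    Returns ``(scores, best)`` where ``best`` maps each method to its winning
    candidate.
    """
    doy_grid = tuple(doy_grid) if doy_grid is not None else DEFAULT_DOY_GRID
    ww, doy, group_starts, catch = _prepare_grid_inputs(traps, weather)
    tmin = ww["tmin_c"].to_numpy()
    tmax = ww["tmax_c"].to_numpy()
    rows = catch["row"].to_numpy()

    scores: list[CandidateModelScore] = []
    for method in methods:
        base = DegreeDayParams(method=method, ldt=ldt, udt=udt, start_doy=1)
        dd_all = np.asarray(daily_dd(tmin, tmax, base), dtype=float)
        for start_doy in doy_grid:
            params = DegreeDayParams(method=method, ldt=ldt, udt=udt, start_doy=start_doy)
            try:
                dd = np.where(doy >= start_doy, dd_all, 0.0)
                cs = np.cumsum(dd)
                offsets = np.repeat(cs[group_starts] - dd[group_starts], np.diff(np.append(group_starts, len(dd))))
                cum = cs - offsets
                data = catch.assign(gdd=cum[rows])
                fit = fit_logistic_gls(data, **fit_kwargs)
                scores.append(score_candidate(data, fit, method=params.method, start_doy=start_doy))
            except (FitError, ValueError) as exc:
                logger.warning("candidate (%s, DOY %d) failed: %s", method, start_doy, exc)
                scores.append(
                    CandidateModelScore(
                        method=params.method, start_doy=start_doy,
                        mae=np.nan, rmse=np.nan, pseudo_r2=np.nan, error=str(exc),
                    )
                )
    ok = [s for s in scores if s.error is None]
    if not ok:
        raise FitError("every candidate model failed to fit")
    best: dict[str, CandidateModelScore] = {}
    for method in methods:
        method = DegreeDayParams(method=method).method
        cands = [s for s in ok if s.method == method]
        if cands:
            best[method] = min(cands, key=lambda s: (s.mae, s.rmse, s.start_doy))
    return scores, best


def year_split_cv(
    data: pd.DataFrame,
    split_seed: int | np.random.Generator | None = 0,
    test_fraction: float = 0.5,
    train_years: tuple | None = None,
    test_years: tuple | None = None,
    direction: str = "observed_on_predicted",
    **fit_kwargs,
) -> ValidationReport:
    """Validate the flight model by splitting site-years on calendar year.

    Years are split at random (seeded) into train and test sets — or passed
    explicitly — the logistic model is fitted on the train-year site-years,
    test-year cumulative proportions are predicted at their observed GDD
    values, and observed values are regressed on predictions by ordinary
    least squares (``direction="predicted_on_observed"`` flips the
    regression).  A perfectly predictive model yields slope 1, intercept 0,
    RMSE 0, R^2 1.
    """
    years = np.array(sorted(data["year"].unique()))
    if train_years is None or test_years is None:
        if len(years) < 2:
            raise ValueError("need at least 2 distinct years to split")
        rng = np.random.default_rng(split_seed)
        shuffled = rng.permutation(years)
        n_test = max(1, int(round(test_fraction * len(years))))
        n_test = min(n_test, len(years) - 1)
        test_years = tuple(sorted(shuffled[:n_test]))
        train_years = tuple(sorted(shuffled[n_test:]))
    train = data[data["year"].isin(train_years)]
    test = data[data["year"].isin(test_years)]
    if len(test) == 0:
        raise ValueError(f"test years {test_years} contain no usable site-years")

    fit = fit_logistic_gls(train, **fit_kwargs)
    observed = test["cum_prop"].to_numpy(dtype=float)
    predicted = np.asarray(predict_cumulative(fit, test["gdd"].to_numpy(dtype=float)))

    if direction == "observed_on_predicted":
        yy, xx = observed, predicted
    elif direction == "predicted_on_observed":
        yy, xx = predicted, observed
    else:
        raise ValueError(f"unknown regression direction {direction!r}")
    ols = sm.OLS(yy, sm.add_constant(xx)).fit()
    resid = observed - predicted
    return ValidationReport(
        train_years=tuple(int(y) for y in train_years),
        test_years=tuple(int(y) for y in test_years),
        slope=float(ols.params[1]),
        intercept=float(ols.params[0]),
        rmse=float(np.sqrt(np.mean(resid**2))),
        r2=float(ols.rsquared),
        mae=float(np.mean(np.abs(resid))),
        pseudo_r2=pseudo_r2(observed, predicted),
    )
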