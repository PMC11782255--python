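"""Cumulative trap-catch flight curves and the heteroskedastic logistic model.

Weekly pheromone-trap counts of migrant adult moths are converted, per
site-year, to the seasonal cumulative proportion of trap catch and placed on
a growing-degree-day (GDD) axis.  The seasonal curve is modelled with a
three-parameter logistic fitted by maximum likelihood under a variance-power
error structure:

    Y_ij = a / (1 + exp(-(x_ij - b)/c)) + eps_ij,
    eps_ij ~ N(0, sigma^2 * |v_ij|^(2*delta)),

where a is the upper asymptote, b the GDD at which the curve reaches half of
a, c a growth-rate (spread) parameter in GDD, and v_ij a per-observation
variance covariate (calendar year by default) whose power delta lets
within-group errors be heteroskedastic across years.  With delta fixed at 0
the fit reduces exactly to ordinary nonlinear least squares.

The GDD at median flight — the biofix for downstream life-stage forecasts —
is the closed-form solution of the fitted curve at 0.5:

    x_0.5 = b - c * ln(a/0.5 - 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "FitError",
    "LogisticFit",
    "cumulative_catch",
    "logistic_curve",
    "fit_logistic_gls",
    "predict_cumulative",
    "median_flight_gdd",
]

logger = logging.getLogger(__name__)

#: Site-years whose seasonal trap total does not exceed this count are
#: excluded from curve fitting (too few moths to define a proportion curve).
MIN_SEASONAL_TOTAL = 20


class FitError(RuntimeError):
    """Raised when the nonlinear fit fails; carries optimizer diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


@dataclass(frozen=True)
class LogisticFit:
    """Fitted three-parameter logistic with variance-power error structure."""

    a: float
    b: float
    c: float
    sigma: float
    delta: float
    cov: np.ndarray = field(repr=False)  # 3x3 covariance of (a, b, c), conditional on delta
    n_obs: int = 0
    loglik: float = np.nan
    converged: bool = True
    n_starts: int = 1
    variance_covariate: str = "year"

    @property
    def se(self) -> tuple[float, float, float]:
        d = np.sqrt(np.clip(np.diag(self.cov), 0, None))
        return float(d[0]), float(d[1]), float(d[2])


def cumulative_catch(
    traps: pd.DataFrame,
    gdd: pd.DataFrame,
    min_total: int = MIN_SEASONAL_TOTAL,
) -> pd.DataFrame:
    """Convert weekly trap counts to cumulative seasonal proportions on a GDD axis.

    Parameters
    ----------
    traps:
        Frame with columns ``site_year_id, year, visit_date, count``.
    gdd:
        Accumulated degree-day series (``site_year_id, date, cumulative_gdd``)
        covering every visit date; visits outside weather coverage raise.
    min_total:
        Site-years whose seasonal total is not strictly greater than this are
        dropped with a logged notice.

    Returns
    -------
    DataFrame ``site_year_id, year, date, gdd, cum_prop`` with cum_prop
    non-decreasing within site-year and ending at 1.
    """
    traps = traps.copy()
    traps["visit_date"] = pd.to_datetime(traps["visit_date"])
    if (traps["count"] < 0).any():
        raise ValueError("trap counts must be non-negative")
    gdd = gdd.copy()
    gdd["date"] = pd.to_datetime(gdd["date"])

    out = []
    for sy, grp in traps.groupby("site_year_id", sort=True):
        grp = grp.sort_values("visit_date")
        total = grp["count"].sum()
        if total <= min_total:
            logger.info("dropping site-year %r: seasonal total %d <= %d", sy, total, min_total)
            continue
        sy_gdd = gdd[gdd["site_year_id"] == sy].set_index("date")["cumulative_gdd"]
        missing = grp.loc[~grp["visit_date"].isin(sy_gdd.index), "visit_date"]
        if len(missing):
            raise ValueError(
                f"visit dates outside weather coverage for site-year {sy!r}: "
                f"{[str(d.date()) for d in missing[:5]]}"
            )
        out.append(
            pd.DataFrame(
                {
                    "site_year_id": sy,
                    "year": grp["year"].to_numpy(),
                    "date": grp["visit_date"].to_numpy(),
                    "gdd": sy_gdd.loc[grp["visit_date"]].to_numpy(dtype=float),
                    "cum_prop": grp["count"].cumsum().to_numpy(dtype=float) / total,
                }
            )
        )
    if not out:
        return pd.DataFrame(columns=["site_year_id", "year", "date", "gdd", "cum_prop"])
    return pd.concat(out, ignore_index=True)


def logistic_curve(x, a: float, b: float, c: float):
    """The three-parameter logistic a / (1 + exp(-(x - b)/c))."""
    z = (np.asarray(x, dtype=float) - b) / c
    return a / (1.0 + np.exp(-np.clip(z, -700, 700)))


def _resolve_covariate(data: pd.DataFrame, variance_covariate) -> np.ndarray:
    if isinstance(variance_covariate, str):
        if variance_covariate == "year_index":
            years = data["year"].to_numpy(dtype=float)
            v = years - years.min() + 1.0
        elif variance_covariate in data.columns:
            v = data[variance_covariate].to_numpy(dtype=float)
        else:
            raise ValueError(f"variance covariate {variance_covariate!r} not found in data")
    else:
        v = np.asarray(variance_covariate, dtype=float)
        if len(v) != len(data):
            raise ValueError("variance covariate length mismatch")
    v = np.abs(v)
    if np.any(v == 0):
        raise ValueError("variance covariate must be nonzero (|v|^delta would degenerate)")
    return v


def _start_values(x: np.ndarray, y: np.ndarray) -> list[tuple[float, float, float]]:
    """Initial (a, b, c) candidates from empirical quantile crossings.

    b starts at the GDD where the curve crosses half its maximum, c at the
    25-75% crossing span divided by 2*ln(3) (the exact relation for a
    logistic), each with coarser/finer variants to guard poor geometry.
    """
    a0 = float(np.clip(np.max(y), 0.5, 1.5))
    order = np.argsort(x)
    xs = x[order]
    ys = np.maximum.accumulate(y[order])  # monotone envelope for crossing lookup

    def crossing(level: float) -> float:
        idx = np.searchsorted(ys, level * a0)
        idx = min(max(idx, 1), len(xs) - 1)
        return float(xs[idx])

    b0 = crossing(0.5)
    span = max(crossing(0.75) - crossing(0.25), 1e-3)
    c0 = span / (2.0 * np.log(3.0))
    starts = [(a0, b0, c0)]
    for fb, fc in ((1.0, 0.5), (1.0, 2.0), (0.85, 1.0), (1.15, 1.0)):
        starts.append((a0, b0 * fb, c0 * fc))
    return starts


def _wls_fit(x, y, sqrt_w, starts):
    """Weighted nonlinear least squares of the logistic; best of multi-start."""

    def resid(theta):
        a, b, c = theta
        return (y - logistic_curve(x, a, b, c)) / sqrt_w

    def jac(theta):
        a, b, c = theta
        z = np.clip((x - b) / c, -700, 700)
        s = 1.0 / (1.0 + np.exp(-z))
        ds = s * (1.0 - s)
        J = np.empty((len(x), 3))
        J[:, 0] = -s
        J[:, 1] = a * ds / c
        J[:, 2] = a * ds * z / c
        return J / sqrt_w[:, None]

    best = None
    for theta0 in starts:
        sol = optimize.least_squares(
            resid, theta0, jac=jac,
            bounds=([1e-6, -np.inf, 1e-6], [np.inf, np.inf, np.inf]),
            xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=2000,
        )
        if best is None or sol.cost < best.cost - 1e-14:
            best = sol
    return best


def fit_logistic_gls(
    data: pd.DataFrame,
    fix_delta: float | None = None,
    variance_covariate: str | np.ndarray = "year",
    delta_bounds: tuple[float, float] = (-2.0, 3.0),
) -> LogisticFit:
    """Fit the heteroskedastic logistic flight-curve model by maximum likelihood.

    Parameters
    ----------
    data:
        Cumulative-catch frame with columns ``gdd`` (x), ``cum_prop`` (y) and
        ``year`` (default variance covariate).
    fix_delta:
        Hold the variance-power exponent fixed (0 recovers ordinary nonlinear
        least squares); ``None`` profiles delta jointly with (a, b, c, sigma).
    variance_covariate:
        ``"year"`` (raw calendar year), ``"year_index"`` (year minus first
        year plus one — recommended when raw years are large and nearly
        constant in relative terms), any other numeric column name, or an
        explicit array.

    Returns
    -------
    LogisticFit with Wald covariance of (a, b, c) conditional on the fitted
    delta, ``sigma`` estimated with an n - 3 denominator, and the maximised
    Gaussian log-likelihood.

    Raises
    ------
    FitError
        On optimizer failure or degenerate data, with diagnostics attached.
    """
    x = data["gdd"].to_numpy(dtype=float)
    y = data["cum_prop"].to_numpy(dtype=float)
    if len(np.unique(x)) < 3:
        raise FitError("need at least 3 distinct GDD values", {"n_unique_x": len(np.unique(x))})
    if np.allclose(y, y[0]):
        raise FitError("degenerate data: all cumulative proportions identical")
    v = _resolve_covariate(data, variance_covariate)
    n = len(x)
    starts = _start_values(x, y)
    log_v = np.log(v)

    state: dict = {}

    def concentrated_nll(delta: float) -> float:
        sqrt_w = v**delta
        warm = [state["theta"]] if "theta" in state else []
        sol = _wls_fit(x, y, sqrt_w, warm + starts)
        state["theta"] = tuple(sol.x)
        state[delta] = sol
        sigma2_ml = 2.0 * sol.cost / n  # cost = 0.5 * sum(weighted res^2)
        if sigma2_ml <= 0:
            sigma2_ml = np.finfo(float).tiny
        return 0.5 * n * np.log(sigma2_ml) + delta * log_v.sum()

    if fix_delta is not None:
        delta = float(fix_delta)
        concentrated_nll(delta)
    else:
        res = optimize.minimize_scalar(
            concentrated_nll, bounds=delta_bounds, method="bounded",
            options={"xatol": 1e-6},
        )
        if not res.success:
            raise FitError("delta profile optimisation failed", {"scalar_result": str(res)})
        delta = float(res.x)
        if delta not in state:
            concentrated_nll(delta)
        if min(delta - delta_bounds[0], delta_bounds[1] - delta) < 1e-3:
            logger.warning(
                "profiled delta=%.3f sits at the search bound %s; with a nearly "
                "constant variance covariate (e.g. raw calendar years) sigma and "
                "delta are jointly weakly identified — consider "
                "variance_covariate='year_index'", delta, delta_bounds,
            )

    sol = state[delta]
    if not sol.success:
        raise FitError(
            "weighted least squares did not converge",
            {"status": sol.status, "message": sol.message, "cost": sol.cost},
        )
    a, b, c = sol.x
    dof = max(n - 3, 1)
    rss_w = 2.0 * sol.cost
    sigma2 = rss_w / dof
    JtJ = sol.jac.T @ sol.jac
    try:
        cov = sigma2 * np.linalg.inv(JtJ)
    except np.linalg.LinAlgError:
        cov = np.full((3, 3), np.nan)
    sigma2_ml = rss_w / n
    loglik = -0.5 * n * (np.log(2 * np.pi * sigma2_ml) + 1.0) - delta * log_v.sum()

    cov_name = variance_covariate if isinstance(variance_covariate, str) else "<array>"
    fit = LogisticFit(
        a=float(a), b=float(b), c=float(c),
        sigma=float(np.sqrt(sigma2)), delta=delta, cov=cov,
        n_obs=n, loglik=float(loglik), converged=True,
        n_starts=len(starts), variance_covariate=cov_name,
    )
    if not (0 < fit.a <= 1.5):
        logger.warning("fitted asymptote a=%.3f outside the plausible (0, 1.5] range", fit.a)
    return fit


def predict_cumulative(fit: LogisticFit, x) -> np.ndarray | float:
    """Predicted cumulative proportion of seasonal flight at GDD ``x``."""
    if not fit.converged:
        raise FitError("cannot predict from an unconverged fit")
    out = logistic_curve(x, fit.a, fit.b, fit.c)
    return float(out) if np.ndim(x) == 0 else out


def median_flight_gdd(
    fit: LogisticFit,
    confidence: float = 0.95,
    n_boot: int = 2000,
    rng: np.random.Generator | int | None = None,
) -> tuple[float, tuple[float, float]]:
    """GDD at which the fitted flight curve crosses 0.5, with a bootstrap CI.

    The point estimate is the closed form ``b - c*ln(a/0.5 - 1)``; the
    interval is a seeded parametric bootstrap from the multivariate-normal
    approximation to the (a, b, c) sampling distribution, which tolerates the
    asymmetry typical of these curves.  Requires a > 0.5 (the curve must
    actually reach the median).
    """
    if fit.a <= 0.5:
        raise ValueError(f"asymptote a={fit.a:.3f} <= 0.5; the curve never reaches median flight")
    point = fit.b - fit.c * np.log(fit.a / 0.5 - 1.0)
    if n_boot <= 0 or not np.all(np.isfinite(fit.cov)):
        return float(point), (np.nan, np.nan)
    rng = np.random.default_rng(rng)
    draws = rng.multivariate_normal([fit.a, fit.b, fit.c], fit.cov, size=n_boot)
    a, b, c = draws[:, 0], draws[:, 1], draws[:, 2]
    ok = (a > 0.5) & (c > 0)
    if ok.sum() < max(50, n_boot // 20):
        logger.warning("only %d/%d bootstrap draws reach median flight", ok.sum(), n_boot)
    x05 = b[ok] - c[ok] * np.log(a[ok] / 0.5 - 1.0)
    alpha = (1.0 - confidence) / 2.0
    lo, hi = np.quantile(x05, [alpha, 1.0 - alpha])
    return float(point), (float(lo), float(hi))
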