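"""Temperature-dependent development: thresholds and thermal constants.

Constant-temperature rearing records (one specimen completing one life stage
at one temperature) are analysed with the classical linear rate-summation
approach: the development rate y = 1/days is regressed on rearing
temperature T per specimen,

    y = a + b*T,

and the lower developmental threshold and thermal constant follow as

    t = -a/b            (°C at which the fitted rate reaches zero)
    k = 1/b             (degree days to complete the stage).

Standard errors use the delta-method expressions

    SE(t) = (ybar/b) * sqrt( s^2/(N*ybar^2) + (SE_b/b)^2 )
    SE(k) = SE_b / b^2,

where s^2 is the residual mean square of y, N the number of specimens and
ybar the mean rate.  Degree-day requirements standardised to a single fixed
threshold (for practical forecasting) are computed per specimen as
days * (T - LDT) and averaged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "StageThermalEstimate",
    "FixedLdtRequirement",
    "fit_stage_rate",
    "fit_all_stages",
    "pooled_ldt",
    "thermal_constant_fixed_ldt",
    "fixed_ldt_table",
]

logger = logging.getLogger(__name__)

DIETS = ("artificial", "perennial_ryegrass", "combined")
STAGES = ("egg", "larva", "pupa", "egg_to_adult", "small_larva", "large_larva")


@dataclass(frozen=True)
class StageThermalEstimate:
    """Linear rate-regression fit for one life stage on one diet.

    ``status`` is ``"ok"`` for a physically sensible fit (b > 0) and
    ``"non_physical"`` when the slope is non-positive, in which case t and k
    are reported as NaN but the raw regression coefficients are retained.
    """

    stage: str
    diet: str
    a: float          # intercept, day^-1
    b: float          # slope, day^-1 °C^-1
    se_b: float
    s2: float         # residual mean square of the rates
    n: int
    ybar: float
    t: float          # lower developmental threshold, °C
    se_t: float
    k: float          # thermal constant, degree days
    se_k: float
    status: str = "ok"
    excluded_temperatures: tuple = ()


@dataclass(frozen=True)
class FixedLdtRequirement:
    """Mean degree-day requirement for a stage at a fixed common threshold."""

    stage: str
    diet: str
    ldt: float
    k_dd: float
    se_k_dd: float
    n: int


def _single_cell(df: pd.DataFrame) -> tuple[str, str]:
    stages = df["stage"].unique()
    diets = df["diet"].unique()
    if len(stages) != 1 or len(diets) != 1:
        raise ValueError(
            f"expected observations for a single stage x diet cell, got stages={list(stages)} diets={list(diets)}"
        )
    return stages[0], diets[0]


def fit_stage_rate(observations: pd.DataFrame) -> StageThermalEstimate:
    """Fit the rate regression for one stage x diet cell of rearing records.

    Parameters
    ----------
    observations:
        Frame with columns ``specimen_id, temperature_c, diet, stage, days,
        completed`` restricted to one stage and one diet.  Temperatures at
        which no specimen completed the stage (complete mortality) are
        excluded automatically with a logged notice; incomplete specimens at
        other temperatures are dropped.

    Raises
    ------
    ValueError
        If fewer than two distinct completed temperatures remain (the
        regression is rank deficient).
    """
    stage, diet = _single_cell(observations)
    completed_any = observations.groupby("temperature_c")["completed"].any()
    excluded = tuple(sorted(completed_any.index[~completed_any]))
    if excluded:
        logger.info(
            "excluding temperatures with complete mortality for %s/%s: %s", stage, diet, list(excluded)
        )
    obs = observations[observations["completed"] & ~observations["temperature_c"].isin(excluded)]
    temps = obs["temperature_c"].to_numpy(dtype=float)
    if len(np.unique(temps)) < 2:
        raise ValueError(f"need >=2 distinct completed temperatures for {stage}/{diet}")
    days = obs["days"].to_numpy(dtype=float)
    if np.any(days <= 0):
        raise ValueError("completed observations must have days > 0")
    rates = 1.0 / days

    res = sm.OLS(rates, sm.add_constant(temps)).fit()
    a, b = res.params
    se_b = res.bse[1]
    s2 = res.mse_resid
    n = len(rates)
    ybar = rates.mean()

    if b <= 0:
        logger.warning("non-physical rate regression (b<=0) for %s/%s", stage, diet)
        return StageThermalEstimate(
            stage, diet, a, b, se_b, s2, n, ybar,
            t=np.nan, se_t=np.nan, k=np.nan, se_k=np.nan,
            status="non_physical", excluded_temperatures=excluded,
        )

    t = -a / b
    k = 1.0 / b
    se_t = (ybar / b) * np.sqrt(s2 / (n * ybar**2) + (se_b / b) ** 2)
    se_k = se_b / b**2
    return StageThermalEstimate(
        stage, diet, a, b, se_b, s2, n, ybar, t, se_t, k, se_k,
        status="ok", excluded_temperatures=excluded,
    )


def fit_all_stages(observations: pd.DataFrame, include_combined: bool = True) -> list[StageThermalEstimate]:
    """Fit every stage x diet cell present; optionally add pooled-diet fits.

    The ``combined`` diet pools all records of a stage across diets, matching
    the convention of reporting a third, diet-agnostic column of estimates.
    """
    fits = []
    for (stage, diet), cell in observations.groupby(["stage", "diet"], sort=True):
        try:
            fits.append(fit_stage_rate(cell))
        except ValueError as exc:
            logger.warning("skipping %s/%s: %s", stage, diet, exc)
    if include_combined and observations["diet"].nunique() > 1:
        for stage, cell in observations.groupby("stage", sort=True):
            pooled = cell.assign(diet="combined")
            try:
                fits.append(fit_stage_rate(pooled))
            except ValueError as exc:
                logger.warning("skipping %s/combined: %s", stage, exc)
    return fits


def pooled_ldt(estimates: list[StageThermalEstimate] | list[float]) -> tuple[float, float]:
    """Unweighted mean lower developmental threshold across stage/diet cells.

    Returns ``(mean_t, se)`` where the SE is the standard error of the mean
    (0 for a single estimate).  Accepts either fitted estimates or bare
    threshold values.
    """
    ts = np.array(
        [e.t if isinstance(e, StageThermalEstimate) else float(e) for e in estimates], dtype=float
    )
    ts = ts[np.isfinite(ts)]
    if len(ts) == 0:
        raise ValueError("no finite threshold estimates to pool")
    mean = ts.mean()
    se = 0.0 if len(ts) == 1 else ts.std(ddof=1) / np.sqrt(len(ts))
    return float(mean), float(se)


def thermal_constant_fixed_ldt(observations: pd.DataFrame, ldt: float) -> FixedLdtRequirement:
    """Degree-day requirement of one stage x diet cell at a fixed threshold.

    Each completed specimen contributes ``days * (temperature - ldt)`` degree
    days; the requirement is the mean across specimens (all rearing
    temperatures pooled) with its standard error.
    """
    stage, diet = _single_cell(observations)
    obs = observations[observations["completed"]]
    if len(obs) == 0:
        raise ValueError(f"no completed observations for {stage}/{diet}")
    temps = obs["temperature_c"].to_numpy(dtype=float)
    if np.any(temps <= ldt):
        raise ValueError(
            f"rearing temperature at or below the fixed LDT {ldt} °C for {stage}/{diet}; degree days undefined"
        )
    dd = obs["days"].to_numpy(dtype=float) * (temps - ldt)
    se = 0.0 if len(dd) == 1 else dd.std(ddof=1) / np.sqrt(len(dd))
    return FixedLdtRequirement(stage, diet, float(ldt), float(dd.mean()), float(se), len(dd))


def fixed_ldt_table(observations: pd.DataFrame, ldt: float, include_combined: bool = True) -> pd.DataFrame:
    """Tabulate fixed-LDT degree-day requirements for every stage x diet cell."""
    rows = []
    cells = [(s, d, c) for (s, d), c in observations.groupby(["stage", "diet"], sort=True)]
    if include_combined and observations["diet"].nunique() > 1:
        cells += [(s, "combined", c.assign(diet="combined")) for s, c in observations.groupby("stage", sort=True)]
    for stage, diet, cell in cells:
        try:
            req = thermal_constant_fixed_ldt(cell, ldt)
        except ValueError as exc:
            logger.warning("skipping %s/%s: %s", stage, diet, exc)
            continue
        rows.append(
            {"stage": req.stage, "diet": req.diet, "ldt": req.ldt,
             "k_dd": req.k_dd, "se_k_dd": req.se_k_dd, "n": req.n}
        )
    return pd.DataFrame(rows)
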