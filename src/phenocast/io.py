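"""CSV/JSON readers and writers, pipeline configuration, and orchestration.

Input schemas (one header row, ISO-8601 dates):

* weather:     ``site_year_id, date, tmin_c, tmax_c``
* traps:       ``site_year_id, year, visit_date, count``
* development: ``specimen_id, temperature_c, diet, stage, days, completed``

All floating-point outputs are serialised at 6 significant digits and every
result report embeds the seed and a hash of the configuration, so repeated
runs with the same configuration are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .degree_days import DegreeDayParams, accumulate_gdd, canonical_method
from .development import fit_all_stages, fixed_ldt_table, pooled_ldt
from .flight_model import cumulative_catch, fit_logistic_gls, median_flight_gdd
from .forecast import StageThresholds, project_stage_windows
from .model_selection import DEFAULT_DOY_GRID, grid_search_biofix, score_candidate, year_split_cv

__all__ = [
    "read_weather_csv",
    "read_trap_csv",
    "read_development_csv",
    "PipelineConfig",
    "run_pipeline",
    "write_json",
]

logger = logging.getLogger(__name__)


class SchemaError(ValueError):
    """A CSV failed schema validation; the message lists offending lines."""


def _require_columns(df: pd.DataFrame, required: tuple[str, ...], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")


def read_weather_csv(path) -> pd.DataFrame:
    """Read and validate a daily weather CSV.

    Rejects rows with tmin_c > tmax_c and duplicate dates within a
    site-year, reporting 1-based data line numbers (header = line 1).
    """
    df = pd.read_csv(path)
    _require_columns(df, ("site_year_id", "date", "tmin_c", "tmax_c"), path)
    df["date"] = pd.to_datetime(df["date"], format="ISO8601")
    bad = df.index[df["tmin_c"] > df["tmax_c"]]
    if len(bad):
        lines = [int(i) + 2 for i in bad[:10]]
        raise SchemaError(f"{path}: tmin_c > tmax_c on line(s) {lines}")
    dup = df.index[df.duplicated(subset=["site_year_id", "date"])]
    if len(dup):
        lines = [int(i) + 2 for i in dup[:10]]
        raise SchemaError(f"{path}: duplicate site-year/date on line(s) {lines}")
    return df.sort_values(["site_year_id", "date"]).reset_index(drop=True)


def read_trap_csv(path) -> pd.DataFrame:
    """Read and validate a weekly trap-count CSV.

    Negative counts are rejected; unsorted visit dates are sorted with a
    warning rather than rejected.
    """
    df = pd.read_csv(path)
    _require_columns(df, ("site_year_id", "year", "visit_date", "count"), path)
    df["visit_date"] = pd.to_datetime(df["visit_date"], format="ISO8601")
    bad = df.index[df["count"] < 0]
    if len(bad):
        lines = [int(i) + 2 for i in bad[:10]]
        raise SchemaError(f"{path}: negative count on line(s) {lines}")
    sorted_df = df.sort_values(["site_year_id", "visit_date"], kind="stable")
    if not sorted_df.index.equals(df.index):
        logger.warning("%s: visit dates were not sorted within site-years; sorting", path)
    return sorted_df.reset_index(drop=True)


def read_development_csv(path) -> pd.DataFrame:
    """Read and validate a constant-temperature rearing CSV."""
    df = pd.read_csv(path)
    _require_columns(df, ("specimen_id", "temperature_c", "diet", "stage", "days", "completed"), path)
    df["completed"] = df["completed"].astype(bool)
    bad = df.index[df["completed"] & ~(df["days"] > 0)]
    if len(bad):
        lines = [int(i) + 2 for i in bad[:10]]
        raise SchemaError(f"{path}: completed specimen without days > 0 on line(s) {lines}")
    return df


# --------------------------------------------------------------------------
# serialisation helpers


def _round_sig(x: float, sig: int = 6) -> float:
    if not np.isfinite(x) or x == 0:
        return float(x)
    return float(f"{x:.{sig}g}")


def _jsonify(obj):
    """Recursively convert to JSON-safe types, rounding floats to 6 s.f."""
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        return _round_sig(float(obj))
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _jsonify(obj.tolist())
    if isinstance(obj, pd.Timestamp):
        return obj.date().isoformat() if obj is not pd.NaT else None
    if obj is pd.NaT:
        return None
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonify(dataclasses.asdict(obj))
    return obj


def write_json(obj, path) -> None:
    """Write a deterministic JSON report (sorted keys, 6-s.f. floats)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(_jsonify(obj), indent=2, sort_keys=True) + "\n")


def write_table_csv(df: pd.DataFrame, path) -> None:
    """Write a tidy CSV with floats at 6 significant digits."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.6g")


# --------------------------------------------------------------------------
# pipeline


@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end run configuration.

    Defaults mirror the selected field model: single-sine degree days from
    DOY 120 with LDT 9.8 °C, the full 5-day biofix grid, a seeded 50/50
    year split for validation, and the combined life-stage preset for the
    forecast.
    """

    weather_path: str = ""
    traps_path: str = ""
    development_path: str | None = None
    out_dir: str = "results"

    ldt: float = 9.8
    method: str = "single_sine"
    start_doy: int = 120
    udt: float | None = None

    run_grid_search: bool = True
    doy_grid: tuple[int, ...] = DEFAULT_DOY_GRID
    grid_fix_delta: float | None = 0.0   # plain NLS over the grid; final fit profiles delta
    variance_covariate: str = "year"
    fix_delta: float | None = None

    cv_seed: int = 0
    cv_test_fraction: float = 0.5
    seed: int = 0
    n_boot: int = 2000
    forecast_preset: str = "combined"

    @classmethod
    def from_toml(cls, path) -> "PipelineConfig":
        import tomllib

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"{path}: unknown configuration keys {sorted(unknown)}")
        if "doy_grid" in raw:
            raw["doy_grid"] = tuple(raw["doy_grid"])
        return cls(**raw)

    def digest(self) -> str:
        """Hash of the analysis-relevant configuration (output location excluded)."""
        fields = dataclasses.asdict(self)
        fields.pop("out_dir", None)
        payload = json.dumps(_jsonify(fields), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis and write result reports.

    Stages: optional development fits (thresholds, thermal constants, pooled
    LDT), biofix grid search, final flight fit at the selected candidate,
    year-split validation, median-flight extraction, and a life-stage
    forecast per site-year using the predicted median flight as the biofix.
    Any stage failure aborts with a stage-labelled error.  Outputs:
    ``results.json``, ``candidates.csv`` and ``forecast.csv`` under
    ``config.out_dir``.
    """
    if not config.traps_path or not config.weather_path:
        raise ValueError("configuration must provide weather_path and traps_path")
    out_dir = Path(config.out_dir)
    results: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "config_digest": config.digest(),
    }

    def stage(name):
        logger.info("pipeline stage: %s", name)

    stage("read inputs")
    weather = read_weather_csv(config.weather_path)
    traps = read_trap_csv(config.traps_path)

    if config.development_path:
        stage("development fits")
        dev = read_development_csv(config.development_path)
        fits = fit_all_stages(dev)
        ldt_mean, ldt_se = pooled_ldt([f for f in fits if f.status == "ok"])
        table = fixed_ldt_table(dev, config.ldt)
        results["development"] = {
            "stage_fits": [
                {"stage": f.stage, "diet": f.diet, "t": f.t, "se_t": f.se_t,
                 "k": f.k, "se_k": f.se_k, "n": f.n, "status": f.status}
                for f in fits
            ],
            "pooled_ldt": {"t": ldt_mean, "se": ldt_se},
            "fixed_ldt_table": table.to_dict(orient="records"),
        }

    method = canonical_method(config.method)
    best_method, best_doy = method, config.start_doy
    if config.run_grid_search:
        stage("biofix grid search")
        scores, best = grid_search_biofix(
            traps, weather, ldt=config.ldt, doy_grid=config.doy_grid, udt=config.udt,
            fix_delta=config.grid_fix_delta, variance_covariate=config.variance_covariate,
        )
        score_frame = pd.DataFrame(
            [{"method": s.method, "start_doy": s.start_doy, "mae": s.mae,
              "rmse": s.rmse, "pseudo_r2": s.pseudo_r2, "error": s.error or ""}
             for s in scores]
        )
        write_table_csv(score_frame.round(6), out_dir / "candidates.csv")
        overall = min(best.values(), key=lambda s: (s.mae, s.rmse, s.start_doy))
        best_method, best_doy = overall.method, overall.start_doy
        results["grid_search"] = {
            "n_candidates": len(scores),
            "best_per_method": {
                m: {"start_doy": s.start_doy, "mae": s.mae, "rmse": s.rmse, "pseudo_r2": s.pseudo_r2}
                for m, s in best.items()
            },
            "selected": {"method": best_method, "start_doy": best_doy},
        }

    stage("final flight fit")
    params = DegreeDayParams(method=best_method, ldt=config.ldt, udt=config.udt, start_doy=best_doy)
    gdd = accumulate_gdd(weather, params)
    data = cumulative_catch(traps, gdd)
    fit = fit_logistic_gls(
        data, fix_delta=config.fix_delta, variance_covariate=config.variance_covariate
    )
    final_score = score_candidate(data, fit, method=best_method, start_doy=best_doy)
    results["flight_fit"] = {
        "method": best_method, "start_doy": best_doy,
        "a": fit.a, "b": fit.b, "c": fit.c, "sigma": fit.sigma, "delta": fit.delta,
        "se": list(fit.se), "n_obs": fit.n_obs, "loglik": fit.loglik,
        "mae": final_score.mae, "rmse": final_score.rmse, "pseudo_r2": final_score.pseudo_r2,
    }

    stage("median flight")
    rng = np.random.default_rng(config.seed)
    x05, (lo, hi) = median_flight_gdd(fit, n_boot=config.n_boot, rng=rng)
    results["median_flight"] = {"gdd": x05, "ci_low": lo, "ci_high": hi}

    stage("year-split validation")
    if data["year"].nunique() >= 2:
        report = year_split_cv(
            data, split_seed=config.cv_seed, test_fraction=config.cv_test_fraction,
            fix_delta=config.fix_delta, variance_covariate=config.variance_covariate,
        )
        results["validation"] = {
            "train_years": [int(y) for y in report.train_years],
            "test_years": [int(y) for y in report.test_years],
            "slope": report.slope, "intercept": report.intercept,
            "rmse": report.rmse, "r2": report.r2,
            "mae": report.mae, "pseudo_r2": report.pseudo_r2,
        }
    else:
        results["validation"] = None

    stage("life-stage forecast")
    thresholds = StageThresholds.preset(config.forecast_preset)
    forecast_rows = []
    for sy, sy_weather in weather.groupby("site_year_id", sort=True):
        sy_gdd = gdd[gdd["site_year_id"] == sy]
        crossed = sy_gdd[sy_gdd["cumulative_gdd"] >= x05]
        if len(crossed) == 0:
            continue
        biofix = pd.Timestamp(crossed["date"].iloc[0])
        fc = project_stage_windows(biofix, sy_weather, thresholds, method=best_method, ldt=config.ldt)
        for _, w in fc.windows.iterrows():
            forecast_rows.append(
                {"site_year_id": sy, "biofix_date": biofix.date().isoformat(),
                 "stage": w["stage"], "checkpoint_dd": w["checkpoint_dd"],
                 "date": w["date"].date().isoformat() if pd.notna(w["date"]) else "",
                 "truncated": fc.truncated}
            )
    forecast_frame = pd.DataFrame(forecast_rows)
    write_table_csv(forecast_frame, out_dir / "forecast.csv")
    results["forecast"] = {
        "preset": config.forecast_preset,
        "n_site_years": int(forecast_frame["site_year_id"].nunique()) if len(forecast_rows) else 0,
    }

    write_json(results, out_dir / "results.json")
    return results
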