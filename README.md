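# phenocast

Degree-day phenology modelling and flight forecasting for *Agrotis ipsilon*
(black cutworm), a migratory moth pest of grass seed and vegetable crops.

Timing matters more than anything else in cutworm management: foliar
insecticides only work on small larvae (instars 1–3), which are present for
a narrow window after the spring migrants arrive and lay eggs. `phenocast`
is a library for building the models that predict that window from daily
temperature data and pheromone-trap monitoring. It is aimed at IPM
researchers and extension modellers who work in Python.

## What it computes

**Development.** From constant-temperature rearing records, the linear
rate-summation model *y* = *a* + *bT* (with *y* = 1/days) gives each life
stage's lower developmental threshold *t* = −*a*/*b* and thermal constant
*k* = 1/*b* with delta-method standard errors, plus degree-day requirements
standardised to a single pooled threshold (9.8 °C).

**Degree days.** Daily heat accumulation above the threshold under three
conventions — simple average, single triangle and single sine (horizontal
cutoff) — accumulated per site-year from a day-of-year biofix.

**Flight.** Weekly trap counts become cumulative seasonal proportions
*Y* on a GDD axis and are fitted with a three-parameter logistic under
variance-power heteroskedasticity,

    Y = a / (1 + exp(−(x − b)/c)) + ε,   ε ~ N(0, σ²·|year|^{2δ}),

by profile maximum likelihood. Median flight, the biofix for stage
forecasts, is x₀.₅ = b − c·ln(a/0.5 − 1) with a parametric-bootstrap CI.

**Selection & validation.** A grid search over 75 candidate models (25
start dates DOY 1–125 × 3 methods) scored by MAE/RMSE/pseudo-R², and
year-split cross-validation with observed-on-predicted regression.

**Forecast.** Calendar windows for egg hatch, small/large larvae, pupae and
next-generation adults, projected from the biofix through fixed degree-day
checkpoints (general, grass-seed and artificial-diet presets).

Because no field dataset ships with the package, a seeded synthetic-data
module generates weather, trap and rearing data with the statistical
structure the methods assume; all tests and the acceptance script run on it.

## Worked example

```python
import numpy as np
from phenocast import (SimConfig, DegreeDayParams, gen_weather, gen_trap_counts,
                       accumulate_gdd, cumulative_catch, fit_logistic_gls,
                       median_flight_gdd)

config = SimConfig(seed=3)                      # 40 site-years, 8 years
weather = gen_weather(config)
traps = gen_trap_counts(config, weather).drop(columns=["plateau_warning"])

params = DegreeDayParams(method="single_sine", ldt=9.8, start_doy=120)
data = cumulative_catch(traps, accumulate_gdd(weather, params))
fit = fit_logistic_gls(data, variance_covariate="year_index")
x05, (lo, hi) = median_flight_gdd(fit, rng=np.random.default_rng(3))
print(f"b = {fit.b:.1f} GDD, median flight {x05:.1f} (95% CI {lo:.1f}-{hi:.1f})")
```

prints

```
b = 269.9 GDD, median flight 270.0 (95% CI 268.4-271.6)
```

i.e. half the season's moths are expected in traps once ~270 growing degree
days (base 9.8 °C, accumulated from DOY 120 under the single-sine method)
have elapsed — the fit recovers the generating curve (b = 270). The
`examples/` directory has one short script per capability (degree days,
development thresholds, flight fitting, biofix search + validation, stage
forecasting), each printing the numbers it computes and what they mean.

A thin CLI wraps the same calls:

```bash
phenocast simulate --seed 3 --out-dir sim
phenocast run --weather sim/weather.csv --traps sim/traps.csv \
              --dev sim/development.csv --out-dir results --seed 3
phenocast forecast --biofix 2024-06-10 --weather sim/weather.csv \
                   --preset combined --out windows.csv
```

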