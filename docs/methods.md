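# Methods

`phenocast` implements a degree-day phenology pipeline for *Agrotis ipsilon*
(black cutworm), a migratory noctuid pest of grass seed and vegetable crops.
The pipeline has five statistical components: temperature-dependent
development estimation, degree-day accumulation, a heteroskedastic logistic
model of seasonal adult flight, biofix (accumulation start date) selection
with year-split validation, and life-stage forecasting. A sixth component,
the synthetic-data generators, provides seeded data with the statistical
structure the methods assume, so every stage is testable without field data.

## Temperature-dependent development

Development rate is assumed linear in temperature over the rearing range.
For each life stage × diet cell, per-specimen rates *y* = 1/days are
regressed on constant rearing temperature *T* by ordinary least squares
(statsmodels), *y* = *a* + *bT*. The lower developmental threshold and
thermal constant follow as *t* = −*a*/*b* and *k* = 1/*b*, with
delta-method standard errors

    SE(t) = (ȳ/b) · sqrt( s²/(N·ȳ²) + (SE_b/b)² ),    SE(k) = SE_b/b²,

where *s*² is the residual mean square, *N* the specimen count and ȳ the
mean rate. Assumptions: rates are homoskedastic and Gaussian around the
line, and the tested temperatures lie in the linear range. Temperatures at
which no specimen completes a stage (complete mortality, as happens at
12 °C for larvae even though 12 °C exceeds the estimated threshold — cold
stress is not pure rate slowdown) are excluded automatically. Fits with
*b* ≤ 0 are returned flagged `non_physical` rather than silently accepted.

A single practicable threshold for forecasting is obtained by unweighted
averaging of the per-cell *t* estimates (`pooled_ldt`); stage × diet cells
are pooled, including the diet-combined refits. Degree-day requirements at
that fixed threshold are computed per specimen as days × (*T* − LDT) and
averaged across all specimens and temperatures of a cell — the simplest
estimator consistent with reporting a per-stage mean ± SE.

## Degree-day accumulation

Daily degree days above the lower threshold (default 9.8 °C) are computed
from daily minima and maxima under three conventions:

- **simple average** — max((tmin+tmax)/2 − LDT, 0), mean first, truncation
  second;
- **single triangle** — area above the threshold of a symmetric triangular
  diurnal trace, (tmax − LDT)² / (2(tmax − tmin)) in the partial case;
- **single sine** — area above the threshold of a sinusoidal trace
  (Baskerville–Emin), (1/π)[(Tm − LDT)(π/2 − θ) + α·cosθ] with
  θ = arcsin((LDT − Tm)/α).

All three coincide when the threshold is at or below tmin and vanish when it
is at or above tmax; each is verified against trapezoid integration of its
diurnal curve to 1e-6 DD. An optional upper threshold is applied as a
horizontal cutoff (the default models use none, reflecting low mortality at
32 °C in rearing). Accumulation starts on a day-of-year biofix (1 Jan = 1,
leap years use calendar DOY); missing days inside a series raise rather
than being interpolated, because silent gaps bias cumulative totals.

## Flight curve

Weekly pheromone-trap counts of adult males proxy the migrant population.
Within each site-year the counts are converted to the cumulative proportion
of the seasonal total; site-years with ≤ 20 seasonal captures are excluded
(too few moths to define a curve; the bound is strict). The cumulative
proportion *Y* at accumulated GDD *x* is modelled as

    Y = a / (1 + exp(−(x − b)/c)) + ε,     ε ~ N(0, σ²·|v|^{2δ}),

where *a* is the upper asymptote, *b* the GDD at half-asymptote, *c* a
spread parameter, and *v* a per-observation variance covariate letting
errors differ across years (variance-power heteroskedasticity). Estimation
is maximum likelihood: for a given δ the weighted nonlinear least-squares
problem in (*a*, *b*, *c*) is solved with `scipy.optimize.least_squares`
(analytic Jacobian, multi-start from the empirical 25/50/75% crossing
points of the curve), σ is concentrated out analytically, and δ is profiled
by bounded scalar minimisation over [−2, 3]. With δ fixed at 0 the fit is
exactly ordinary nonlinear least squares, which the tests verify against an
independent `curve_fit` oracle. The reported covariance of (*a*, *b*, *c*)
is the Wald form σ̂²(JᵀWJ)⁻¹ conditional on δ̂ (the same convention as
generalised least-squares fitters in the R ecosystem); σ̂ uses an *n* − 3
denominator. Non-convergence raises with diagnostics, never silently.

The variance covariate is configurable: raw calendar year (the default, for
fidelity to the original formulation), a year index (year − first year + 1),
or any numeric column. With raw ~2000-magnitude years, |v|^{2δ} is nearly
constant across observations, so σ and δ are jointly weakly identified and
the profiled δ tends to a bound while leaving (*a*, *b*, *c*), the fitted
curve and the Wald covariance essentially unchanged; a warning is emitted
and the year-index transform is recommended whenever δ must itself be
interpreted. Simulation studies here use the year index throughout.

Median flight — the GDD at which the curve crosses 0.5, used as the biofix
of adult arrival and oviposition — has the closed form
x₀.₅ = *b* − *c*·ln(*a*/0.5 − 1), defined only when *a* > 0.5. Its interval
is a seeded parametric bootstrap (default 2,000 multivariate-normal draws
from the parameter covariance, percentile interval), chosen over the delta
method because the transformation is asymmetric in *a*.

## Biofix selection and validation

Candidate models are all combinations of the three degree-day methods with
accumulation start dates DOY 1–125 in 5-day steps (25 dates, 75
candidates). Each candidate is fitted and scored on the fitting data with
MAE, RMSE and pseudo-R² = 1 − Σ(y−ŷ)²/Σ(y−ȳ)², pooling all site-year visit
points. The best candidate per method minimises MAE, with ties broken by
lower RMSE and then earlier start date. The search fits candidates with
δ = 0 by default (plain least squares): the ranking metrics are unweighted,
so the variance model does not affect them through the loss, and the final
model is refitted with δ profiled. Because only the GDD axis changes
between candidates, the trap side (cumulative proportions, visit
positions) is computed once and daily degree days per method are reused
across start dates, making the 75-candidate search run in ~1.5 s.

Validation randomly splits calendar years 50/50 (seeded, fraction
configurable) into train and test sets, fits on train-year site-years,
predicts test-year proportions at their observed GDD values, and regresses
observed on predicted (direction configurable) by OLS, reporting slope,
intercept, RMSE of the raw prediction errors, and R². With train = test
the report reproduces in-sample scores exactly, which the tests assert.

## Life-stage forecasting

Forecasts accumulate degree days from a biofix date (typically the date a
site-year's GDD series crosses the predicted median flight) and mark each
stage boundary at the first date whose cumulative degree days reach that
stage's checkpoint. Accumulation starts the day after the biofix, so at a
constant *d* DD/day a checkpoint *C* falls ⌈*C*/*d*⌉ days after the biofix.
Three presets carry the rearing-derived requirements at LDT 9.8 °C:
**combined** (general model: egg 75.72; small larva +142.16; large larva
+230.28; pupa +186.67; egg-to-adult 648.47 DD, the small/large split at the
instar-3/4 boundary), **perennial ryegrass** (grass-seed model: larva
315.92, pupa 178.64, egg-to-adult 601.98) and **artificial** (larva 384.08,
pupa 193.22, egg-to-adult 658.71). The diet-specific presets borrow the
combined egg requirement, since insufficient egg laying precluded
diet-specific egg estimates. Per-stage sums and the directly estimated
egg-to-adult total differ slightly (634.83 vs 648.47 combined) because the
per-specimen estimator is not additive across stages; both are exposed. If
weather runs out before a checkpoint, the forecast is returned truncated
with remaining dates missing, never extrapolated.

## Synthetic data

The generators emulate the study conditions: 40 site-years spread over 8
calendar years; a temperate-valley temperature climatology (annual mean
12 °C, seasonal amplitude 8 °C peaking in mid-July, diurnal range 12 °C,
day-to-day noise SD 2.5 °C, and a per-site-year climate anomaly SD 1.5 °C
representing inter-annual variation — the feature that makes the
accumulation start date identifiable, since without it all site-years
accrue nearly identical pre-biofix heat); a flight curve with a = 1,
b = 270 GDD, c = 30 GDD on a single-sine, LDT 9.8, DOY-120 axis with
σ = 0.05, δ = 0.5 on the year index; weekly visits DOY 130–290 with an
expected seasonal total of 150 moths; and a rearing design of five constant
temperatures (12–32 °C) × two diets × 20 specimens, rates (T − t)/k with a
15% coefficient-of-variation Gaussian noise (relative noise keeps
realism across stages whose mean rates differ five-fold), non-positive
draws redrawn, and designated complete failure at 12 °C.

Two trap-side generators serve different purposes. `gen_trap_counts`
produces realistic integer counts: the logistic curve is distorted by
year-scaled Gaussian noise, made monotone, and weekly increments are
realised as Poisson counts scaled to the seasonal total (totals ≤ 20 are
redrawn). `gen_cumulative_catch` emits (GDD, proportion) points carrying
exactly the regression's independent-Gaussian error structure, which is
what parameter-recovery and interval-coverage studies must see; its points
are intentionally not forced monotone. What passing tests show is that the
estimators recover the truth under the model's own assumptions plus a
realistic count-realisation layer; they do not certify behaviour under
trap-interference, identification error, multi-brood seasons or migration
pulses absent from the generator.

## Numerical choices and limitations

- Logistic starts: b from the half-maximum crossing of the monotone
  envelope of the data, c from the quartile crossing span / 2·ln 3, with
  ×0.5/×2 spread variants; bounds a, c > 0.
- δ profile: bounded Brent on [−2, 3], warm-started inner solves,
  tolerance 1e-6; inner least-squares tolerances 1e-12.
- The asymptote is not constrained to ≤ 1; a post-fit check warns outside
  (0, 1.5].
- Seasonal-total filter boundary is strict (> 20).
- All file outputs round floats to 6 significant digits and embed seed and
  config hash; rerunning a configuration reproduces reports byte-for-byte.
- Problem sizes in the shipped studies (100 recovery replicates of 40
  site-years; 50 grid-search replicates; 10,000 bootstrap resamples) were
  chosen to keep the full suite around two minutes on one CPU while leaving
  Monte-Carlo error well below the asserted margins.
- Out of scope: raster/geospatial weather extraction, double-sine and
  intermediate-cutoff degree-day variants, curvilinear development models
  and upper-threshold estimation, information-criterion model selection,
  and migration-trajectory modelling.
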