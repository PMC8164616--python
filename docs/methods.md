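# Methods

## Design and estimator

The analysis is a time-stratified case-crossover executed at the daily-count
level. Every calendar date belongs to exactly one stratum
`(year, month, ISO weekday)`; a stratum therefore holds 4 or 5 dates, and
comparisons are made only within strata, which removes long-term trend,
seasonality and day-of-week structure by design rather than by modelling.
There is no individual-level referent sampling: the outcome is the daily
count per (disease chapter, patient stratum).

For one grid cell (chapter, patient stratum, pollutant, lag ℓ) the model is
a Poisson regression with stratum fixed effects,

    log mu_t = alpha_s(t) + beta * x_{t-l} + gamma' B_temp(temp_{t-l}) + delta' B_rh(rh_{t-l}),

estimated through the conditional likelihood

    l = sum_s [ sum_{t in s} y_t eta_t - Y_s log sum_{t in s} exp(eta_t) ],

which eliminates `alpha_s` exactly (the within-stratum distribution of
counts given the total `Y_s` is multinomial). The conditional maximum
coincides with the unconditional fixed-effects Poisson fit in both the slope
and its standard error; the test suite verifies this equivalence against an
independent generalized-linear-model fit with stratum indicator variables to
1e-6 relative tolerance.

Numerics: the design matrix columns are standardised internally for
conditioning (estimates are reported back on the concentration scale);
per-stratum log-sum-exp uses a max-shift; Newton steps solve the observed
information system, with step-halving (up to 30 halvings) whenever a step
would decrease the likelihood; convergence is a relative log-likelihood
change below 1e-8 or 100 iterations. Standard errors come from the inverse
observed information. A dataset whose exposure is constant within every
stratum is rejected as non-identified. Strata with zero total count or fewer
than two retained days are dropped — they contribute nothing to the
conditional likelihood. Missing exposure or weather days are handled by
complete-case deletion, counted in the dataset diagnostics.

Significance uses the two-sided Wald test `p = 2(1 - Phi(|beta/se|))`, with
strict thresholds (p exactly 0.05 is not significant). Relative risks are
`exp(beta * Delta)` with Wald 95% intervals; the default increment Δ is the
interquartile range of the pollutant's observed daily series (configurable
to any fixed step), since a slope per single unit is rarely interpretable
across pollutants measured in ppm, ppb and ug/m3. Units are declared per
pollutant and never converted implicitly.

## Weather adjustment

Temperature and relative humidity enter as natural cubic splines of the
identically lagged series. The basis is the truncated-power natural-spline
construction: boundary knots at the observed min/max, interior knots at
equally spaced quantiles, `df` columns spanning exactly the cubic splines
that are linear beyond the boundary; `df = 1` degenerates to the linear
term. The default is 3 df per weather variable — a common choice for daily
time-series health models, kept deliberately small because the time strata
already absorb seasonal structure; it is a configuration parameter and is
recorded in the run log.

## Exposures

Eight exposures are analysed: six measured pollutants (CO ppm; NO2, O3, SO2
ppb; PM2.5 ug/m3; plus the daily maximum 8-h ozone O3H8) and two composite
indices. AQHI is computed from NO2, O3 and PM2.5 as

    AQHI = (10/10.4) * 100 * [(e^{0.000871 NO2} - 1) + (e^{0.000537 O3} - 1) + (e^{0.000487 PM2.5} - 1)],

with the coefficients (from the mortality-risk calibration in large Canadian
cities that defines the operational index) exposed as overridable constants.
AQHIX replaces O3 by O3H8. The index is used as a continuous exposure — the
operational rounding to a 1–10+ scale would discard information and is not
applied. A day missing any constituent has a missing index.

The daily maximum 8-h mean is computed over windows starting at hours
00:00–16:00 (17 windows fully inside the calendar day); a window is valid
with at least 6 of its 8 hours present, and a day with no valid window is
missing. Both conventions are arguments of `daily_max_8h`.

Lagging shifts a daily series so the value on day *d* is the original at
*d − ℓ*, ℓ ∈ [0, 14]; exposure and both weather series are always lagged by
the same ℓ.

## Patient strata

Eighteen subgroups in fixed reporting order: three sex-only strata (All,
Female, Male), six season × sex (warm = April–September, cold =
October–March), nine age band × sex. Age bands are 0–10, 11–60, 61+; the
upper band keeps the conventional label "Age 60+" but the cut defaults to 61
and is configurable (`age_band(..., elderly_start=...)`), reflecting an
ambiguity between the two conventions in published summaries of this
design. Age and season filters are never combined.

## Synthetic data generator

The generator emulates the study conditions at desk scale:

* **Pollutants** — `max(0, mean + amplitude·sin(2π·doy/365.25 + phase) + AR(1) noise)`
  per pollutant, defaults sized to urban Canadian daily series (e.g. NO2
  mean 20 ppb, seasonal amplitude 5, AR coefficient 0.6, innovation sd 4).
  The period is fixed at 365.25 d; phases are configurable. Optional i.i.d.
  Bernoulli missingness (off by default) exercises complete-case handling.
  AQHI/AQHIX are computed from the simulated constituents, not simulated
  directly.
* **Weather** — sinusoidal temperature (mean 8 °C, amplitude 12 °C, sd 3)
  plus Gaussian noise; RH as mean 70% + noise truncated to [0, 100].
* **Counts** — Poisson with
  `log mu = log(baseline) + log(dow factor) + month shift + beta·x_{t-l} + s(temp) + s(rh)`;
  baseline 20 visits/day, flat day-of-week factors, month-level intercept
  shifts N(0, 0.1) on the log scale (absorbed by the conditioning), and
  planted smooth weather terms that default to zero — the strength of
  weather confounding is deliberately a free parameter because no canonical
  value exists for it. All planted functions are recorded in the output
  metadata sidecar.
* **Strata** — the chapter-level series is split across the six sex × age
  cells by a fixed multinomial (proportions roughly matching ED-visit
  demographics), so subgroup counts sum exactly to "All"; season strata are
  date subsets.

All randomness flows through numpy's PCG64 `default_rng`, seeded from the
config with stable per-stream keys (SHA-256 of the stream name), so
identical config + seed is bit-identical across processes; the generator
name and seed are recorded in the metadata.

What the generator does **not** emulate: real concentration distributions
and inter-pollutant correlation structure (pollutants are independent given
their shared seasonal form), diagnostic coding noise, population drift,
holidays, or exposure measurement error. Passing tests therefore establish
that the estimator and aggregation are correct and calibrated under the
stated generative model — not that any particular real-world association
holds. One realistic artefact does appear: pollutants sharing a seasonal
phase are correlated within strata, so single-pollutant models of a
pollutant correlated with the truly causal one show elevated
positive-significant rates, as they do in real multi-pollutant settings.

## Matrices and summaries

The binary matrix rule is `1 iff beta > 0 and p < threshold` (default 0.05);
negative and non-significant associations are both 0. Non-converged or
missing fits contribute 0 but are tallied in a diagnostics report rather
than silently absorbed. The threshold is a parameter so the p < 0.001
sensitivity analysis reuses the same code path; the persistence ratio is
`100·b/a` where `a` and `b` are association counts at 0.05 and 0.001
(undefined when a = 0). Chapter matrices are summed cellwise (order
invariant, exact integer arithmetic).

The counting summary reports per-stratum row totals over the 15 lags, the
maximum row total, the total count of positive associations, and two
percentage rows: associations as a share of all tested cells
(total / (18·15·n_chapters) · 100) and the share of the 270 (stratum, lag)
cells with at least one associated chapter. Both are given because published
tables of this design are ambiguous about which denominator their
percentage row uses.

Heatmap export uses a linear green→red ramp with the numeric value printed
in every cell; the CSV, not the colours, is the contract.

## Pipeline scale and runtime choices

The default grid is 8 exposures × 18 strata × 15 lags × 12 chapters =
25,920 models. The acceptance script runs this full grid on a two-year
(730-day) synthetic series — about 7 ms per fit, a few minutes in total —
and its replicate studies use 500 null fits at 400 days and 200 recovery
fits at 1200 days. The statistical test suite uses 400 replicates per
planted-effect combination at 1200 days: within-2-SE recovery is a
calibration property, so moderate series lengths suffice, and 400
replicates put the binomial noise of the observed recovery fraction well
below the margin between the nominal 95.45% and the 93% pass bound.

Under the null, only *positive* significant slopes enter the matrices, so
the expected marked-cell rate at p < 0.05 is α/2 = 2.5%, and the
calibration tests use that one-sided rate.

## Known limitations

* Single-lag, single-pollutant models only — no distributed-lag or
  multi-pollutant joint models, matching the design this package implements.
* No overdispersion correction; the conditional Poisson variance model is
  taken as given (synthetic data are exactly Poisson; real counts may not
  be).
* No multiple-testing correction beyond the two fixed thresholds — the
  grid tests thousands of hypotheses and the matrices should be read as a
  screening visualisation, not confirmatory inference.
* Station-level averaging is out of scope: the pipeline consumes an
  already-averaged city-level exposure series.
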