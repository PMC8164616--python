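# aircrossover

Time-stratified case-crossover analysis of daily event counts against lagged
air-pollution exposures.

Short-term air-pollution epidemiology asks whether days with elevated
concentrations of pollutants such as NO₂, O₃, PM₂.₅ or composite indices
(AQHI) see more health events — emergency-department visits, here — than
comparable nearby days. This package implements that analysis end to end for
researchers who have daily count series stratified by patient subgroup and
daily (or hourly) pollutant and weather series, and for anyone who wants to
study the design's statistical behaviour on synthetic data with known
planted effects.

## The model

Daily counts are grouped into calendar strata *s* of the form
`year : month : day-of-week`, so a case day is compared only with the 3–4
other same-weekday days of its month (time-stratified referent selection,
which removes trend, seasonality and weekday patterns by design). Within
this design the counts follow a conditional Poisson model

```
y_t ~ Poisson(μ_t),   log μ_t = α_s(t) + β x_(t−ℓ) + γ' ns(temp_(t−ℓ)) + δ' ns(RH_(t−ℓ))
```

where `x` is the pollutant concentration at lag ℓ ∈ [0, 14], `ns(·)` are
natural cubic spline bases of lagged temperature and relative humidity, and
the stratum intercepts `α_s` are eliminated by conditioning on the stratum
totals — the conditional likelihood is maximised directly by Newton
iteration and equals the fixed-effects Poisson fit with one indicator per
stratum. `exp(βΔ)` is the relative risk of a visit for a concentration
increase Δ.

One such model is fitted per cell of a grid: 12 ICD-10 disease chapters × 18
patient strata (sex × age band × season) × 8 exposures (CO, NO₂, O₃, the
daily maximum 8-h ozone O₃H8, PM₂.₅, SO₂, AQHI, AQHIX) × 15 lags — 2160
models per chapter, 25,920 in all. For each (chapter, pollutant) the results
are condensed into an 18 × 15 binary matrix (1 where β̂ > 0 with p < 0.05),
and the 12 chapter matrices are summed cellwise into a 0–12 frequency grid
per pollutant showing how many disease groups are positively associated at
each (stratum, lag).

AQHI is the Canadian composite index
`(10/10.4)·100·[(e^{c₁·NO₂}−1) + (e^{c₂·O₃}−1) + (e^{c₃·PM₂.₅}−1)]`;
AQHIX substitutes O₃H8 for O₃.

Because real ED-visit records are confidential, the package ships a
synthetic-data generator (`aircrossover.simulate`) producing seasonal,
autocorrelated pollutant series, weather series, and Poisson counts whose
log-rate contains a planted slope β at a chosen lag — so estimation,
calibration and aggregation can all be validated against known truth.

## Worked example

`examples/02_simulate_and_fit.py` simulates two years of daily data with a
planted effect of β = 0.02 per ppb NO₂ at lag 1 and refits it:

```
rows: 729   time strata: 168
beta-hat = 0.01996 per ppb (planted 0.02)
SE = 0.00153   two-sided p = 7.70e-39
RR per IQR (7.3 ppb) = 1.157 (95% CI 1.132-1.182)
```

The fitted slope recovers the planted 0.02 within a fraction of a standard
error; the relative risk says visits rise ≈ 15.7% per interquartile-range
increase in previous-day NO₂. The other examples cover the AQHI/O₃H8
computations and a small multi-chapter run with association matrices and the
counting summary.

A thin CLI wraps the same library:

```
aircrossover simulate --out simdir --seed 1
aircrossover run --config config.yaml
aircrossover summarize --results outdir/results.csv
```

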