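"""Synthetic pollutant, weather and count series with known planted structure.

Real emergency-department records and monitoring-network series are
confidential or access-restricted, so every estimation stage here is
exercised against simulated data whose generative model is fully recorded:

* pollutants: annual sinusoid (period 365.25 d) plus AR(1) Gaussian noise,
  clipped at zero;
* weather: sinusoidal temperature with Gaussian noise; relative humidity as
  mean + noise truncated to [0, 100];
* counts: Poisson draws whose log-rate holds a baseline, multiplicative
  day-of-week factors, month-level intercept shifts, smooth (quadratic)
  weather terms and a log-linear effect beta of one pollutant at one lag --
  the planted analogue of the slope the case-crossover model estimates.

Counts for the 18 patient strata are obtained by multinomially splitting a
chapter-level series across sex x age cells with fixed proportions, so
subgroup counts always sum to the "All" series; season strata are date
subsets.  All randomness flows through one named generator (numpy PCG64)
seeded from the config, and identical config + seed gives bit-identical
output.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .exposure import ExposureSeries, POLLUTANT_UNITS, aqhi_series
from .strata import enumerate_patient_strata, assign_season, AGE_BANDS, SEXES

RNG_NAME = "numpy PCG64 (default_rng)"
SEASON_PERIOD_DAYS = 365.25


class ConfigError(ValueError):
    """Raised for invalid simulation configuration."""


@dataclass
class PollutantParams:
    """AR(1)-plus-sinusoid generator parameters for one pollutant."""

    mean: float
    amplitude: float = 0.0
    phase: float = 0.0
    ar: float = 0.0            # lag-1 autocorrelation of the noise process
    sd: float = 1.0            # innovation standard deviation
    missing_rate: float = 0.0  # i.i.d. Bernoulli deletion, off by default

    def validate(self, name: str) -> None:
        if not (-1.0 < self.ar < 1.0):
            raise ConfigError(f"{name}: AR(1) coefficient must be in (-1, 1)")
        if self.sd < 0:
            raise ConfigError(f"{name}: noise sd must be >= 0")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ConfigError(f"{name}: missing_rate must be in [0, 1)")


@dataclass
class WeatherParams:
    temp_mean: float = 8.0        # degC, mid-latitude urban annual mean
    temp_amplitude: float = 12.0  # degC, summer-winter half-range
    temp_phase: float = -np.pi / 2  # peak in midsummer
    temp_sd: float = 3.0
    rh_mean: float = 70.0         # percent
    rh_sd: float = 10.0

    def validate(self) -> None:
        if not (0.0 <= self.rh_mean <= 100.0):
            raise ConfigError("RH mean must lie in [0, 100]")
        if self.temp_sd < 0 or self.rh_sd < 0:
            raise ConfigError("weather noise sd must be >= 0")


@dataclass
class EffectParams:
    """The planted exposure effect: slope beta at a single lag."""

    pollutant: str = "NO2"
    lag: int = 0
    beta: float = 0.0

    def validate(self) -> None:
        if not (0 <= self.lag <= 14):
            raise ConfigError("effect lag must be in [0, 14]")


def _default_pollutants() -> dict:
    # Rough magnitudes of urban Canadian daily series on their native scales.
    return {
        "CO": PollutantParams(mean=0.4, amplitude=0.1, ar=0.5, sd=0.08),
        "NO2": PollutantParams(mean=20.0, amplitude=5.0, ar=0.6, sd=4.0),
        "O3": PollutantParams(mean=25.0, amplitude=10.0, phase=-np.pi / 2,
                              ar=0.5, sd=6.0),
        "O3H8": PollutantParams(mean=33.0, amplitude=12.0, phase=-np.pi / 2,
                                ar=0.5, sd=7.0),
        "PM25": PollutantParams(mean=8.0, amplitude=2.0, ar=0.5, sd=3.0),
        "SO2": PollutantParams(mean=2.5, amplitude=0.5, ar=0.4, sd=1.0),
    }


@dataclass
class SimulationConfig:
    n_days: int = 730
    start_date: str = "2004-04-01"
    seed: int = 0
    pollutant_params: dict = field(default_factory=_default_pollutants)
    weather_params: WeatherParams = field(default_factory=WeatherParams)
    effect: EffectParams = field(default_factory=EffectParams)
    baseline_rate: float = 20.0     # expected daily count at reference
    dow_effects: tuple = (1.0,) * 7  # multiplicative, ISO order Mon..Sun
    # Smooth planted weather confounding on the log-rate (quadratic in
    # centred temperature / RH); zero by default.
    temp_effect: tuple = (0.0, 0.0)
    rh_effect: tuple = (0.0, 0.0)
    month_effect_sd: float = 0.1    # log-scale month-level intercept shifts
    # Fixed sex x age multinomial split of the chapter series (rows Female,
    # Male x bands 0-10, 11-60, 61+); must sum to 1.
    subgroup_proportions: dict = field(default_factory=lambda: {
        ("female", "0-10"): 0.06, ("female", "11-60"): 0.30,
        ("female", "61+"): 0.15,
        ("male", "0-10"): 0.07, ("male", "11-60"): 0.28,
        ("male", "61+"): 0.14,
    })

    def validate(self) -> None:
        if self.n_days < 60:
            raise ConfigError("n_days must be >= 60 (two calendar months)")
        if self.baseline_rate <= 0:
            raise ConfigError("baseline_rate must be > 0")
        if len(self.dow_effects) != 7 or any(f <= 0 for f in self.dow_effects):
            raise ConfigError("dow_effects must be 7 positive factors")
        for name, p in self.pollutant_params.items():
            p.validate(name)
        self.weather_params.validate()
        self.effect.validate()
        total = sum(self.subgroup_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError("subgroup proportions must sum to 1")

    def dates(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start_date, periods=self.n_days, freq="D")

    def rng(self, stream: str) -> np.random.Generator:
        """Independent named substream of the config seed.

        Stream names are hashed with a stable digest so the mapping from
        (seed, stream) to RNG state is identical across processes.
        """
        digest = hashlib.sha256(stream.encode()).digest()
        key = int.from_bytes(digest[:4], "little")
        ss = np.random.SeedSequence([self.seed, key])
        return np.random.default_rng(ss)


def _seasonal(dates: pd.DatetimeIndex, amplitude: float, phase: float
              ) -> np.ndarray:
    doy = dates.dayofyear.to_numpy(dtype=float)
    return amplitude * np.sin(2 * np.pi * doy / SEASON_PERIOD_DAYS + phase)


def _ar1(n: int, ar: float, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary AR(1) path with innovation sd and lag-1 coefficient ar."""
    if sd == 0:
        return np.zeros(n)
    e = np.empty(n)
    marginal_sd = sd / np.sqrt(1.0 - ar**2)
    e[0] = rng.normal(0.0, marginal_sd)
    innov = rng.normal(0.0, sd, size=n - 1)
    for t in range(1, n):
        e[t] = ar * e[t - 1] + innov[t - 1]
    return e


def simulate_pollutants(config: SimulationConfig) -> dict[str, ExposureSeries]:
    """One ExposureSeries per configured pollutant: sinusoid + AR(1), clipped at 0."""
    config.validate()
    dates = config.dates()
    out = {}
    for name in sorted(config.pollutant_params):
        p = config.pollutant_params[name]
        rng = config.rng(f"pollutant:{name}")
        vals = np.maximum(
            0.0,
            p.mean + _seasonal(dates, p.amplitude, p.phase)
            + _ar1(len(dates), p.ar, p.sd, rng),
        )
        if p.missing_rate > 0:
            drop = rng.random(len(dates)) < p.missing_rate
            vals = np.where(drop, np.nan, vals)
        out[name] = ExposureSeries(
            name, pd.Series(vals, index=dates),
            units=POLLUTANT_UNITS.get(name, ""))
    return out


def simulate_weather(config: SimulationConfig) -> pd.DataFrame:
    """Daily temperature (degC) and relative humidity (%) series."""
    config.validate()
    w = config.weather_params
    dates = config.dates()
    rng_t = config.rng("weather:temp")
    rng_h = config.rng("weather:rh")
    temp = (w.temp_mean + _seasonal(dates, w.temp_amplitude, w.temp_phase)
            + rng_t.normal(0.0, w.temp_sd, size=len(dates)))
    rh = np.clip(w.rh_mean + rng_h.normal(0.0, w.rh_sd, size=len(dates)),
                 0.0, 100.0)
    return pd.DataFrame({"temp": temp, "rh": rh}, index=dates)


@dataclass
class CountSeries:
    """Daily event counts for one (chapter, stratum) combination."""

    chapter: str
    stratum_label: str
    data: pd.Series
    metadata: dict = field(default_factory=dict)


def _log_rate(config: SimulationConfig, exposure: ExposureSeries,
              weather: pd.DataFrame, dates: pd.DatetimeIndex,
              month_shifts: dict) -> np.ndarray:
    eff = config.effect
    x = exposure.data.shift(eff.lag).reindex(dates).to_numpy()
    temp = weather["temp"].shift(eff.lag).reindex(dates).to_numpy()
    rh = weather["rh"].shift(eff.lag).reindex(dates).to_numpy()

    w = config.weather_params
    t_c = temp - w.temp_mean
    h_c = rh - w.rh_mean
    a1, a2 = config.temp_effect
    b1, b2 = config.rh_effect
    dow = np.asarray(config.dow_effects)[dates.weekday.to_numpy()]
    months = dates.month.to_numpy()
    shifts = np.array([month_shifts[m] for m in months])
    return (np.log(config.baseline_rate) + np.log(dow) + shifts
            + eff.beta * x + a1 * t_c + a2 * t_c**2 + b1 * h_c + b2 * h_c**2)


def simulate_counts(config: SimulationConfig, exposure: ExposureSeries,
                    weather: pd.DataFrame) -> CountSeries:
    """Chapter-level daily counts from the planted log-linear Poisson model.

    Days whose lagged exposure or weather is unavailable (the first ``lag``
    days of the span, or injected missingness) are dropped from the output.
    """
    config.validate()
    dates = config.dates()
    rng_m = config.rng("counts:month")
    month_shifts = {m: (rng_m.normal(0.0, config.month_effect_sd)
                        if config.month_effect_sd > 0 else 0.0)
                    for m in range(1, 13)}
    log_mu = _log_rate(config, exposure, weather, dates, month_shifts)
    ok = np.isfinite(log_mu)
    n_dropped = int((~ok).sum())

    rng_c = config.rng("counts:draw")
    # Draw over the full span for stream stability, then mask invalid days.
    mu = np.where(ok, np.exp(log_mu), 0.0)
    counts = rng_c.poisson(mu)
    series = pd.Series(counts[ok], index=dates[ok])
    meta = {
        "rng": RNG_NAME,
        "seed": config.seed,
        "planted_beta": config.effect.beta,
        "planted_lag": config.effect.lag,
        "effect_pollutant": config.effect.pollutant,
        "baseline_rate": config.baseline_rate,
        "dow_effects": list(config.dow_effects),
        "temp_effect": list(config.temp_effect),
        "rh_effect": list(config.rh_effect),
        "month_shifts": {int(k): float(v) for k, v in month_shifts.items()},
        "n_days_dropped_missing_lag": n_dropped,
    }
    return CountSeries("ALL", "All", series, metadata=meta)


def split_counts_by_strata(config: SimulationConfig, chapter_counts: CountSeries
                           ) -> dict[str, CountSeries]:
    """Split a chapter series into the 18 patient-stratum series.

    The daily total is divided across the six sex x age cells by a fixed
    multinomial, so subgroup counts sum exactly to the "All" series; season
    strata restrict to warm/cold dates.
    """
    config.validate()
    rng = config.rng("counts:split")
    dates = chapter_counts.data.index
    totals = chapter_counts.data.to_numpy()
    cells = [(s, b) for s in SEXES for b in AGE_BANDS]
    probs = np.array([config.subgroup_proportions[c] for c in cells])
    draws = rng.multinomial(totals, probs)   # (n_days, 6)
    cell_series = {c: pd.Series(draws[:, j], index=dates)
                   for j, c in enumerate(cells)}

    seasons = np.array([assign_season(d) for d in dates])
    out = {}
    for stratum in enumerate_patient_strata():
        mask = np.ones(len(dates), dtype=bool)
        if stratum.season_filter != "all":
            mask &= seasons == stratum.season_filter
        total = sum(
            cell_series[(sex, band)]
            for sex in SEXES if stratum.sex_filter in ("all", sex)
            for band in AGE_BANDS if stratum.age_filter in ("all", band)
        )
        out[stratum.label] = CountSeries(
            chapter_counts.chapter, stratum.label, total[mask],
            metadata=chapter_counts.metadata)
    return out


def compute_indices(series: dict[str, ExposureSeries]) -> dict[str, ExposureSeries]:
    """Add AQHI and AQHIX series computed from simulated constituents."""
    out = dict(series)
    if {"NO2", "O3", "PM25"} <= series.keys():
        out["AQHI"] = aqhi_series(series["NO2"], series["O3"], series["PM25"])
    if {"NO2", "O3H8", "PM25"} <= series.keys():
        s = aqhi_series(series["NO2"], series["O3H8"], series["PM25"],
                        use_o3h8=True)
        s.pollutant_id = "AQHIX"
        out["AQHIX"] = s
    return out


def write_simulation(config: SimulationConfig, outdir) -> dict:
    """Run the full generator and write CSVs plus a JSON truth sidecar."""
    from pathlib import Path
    from .exposure import write_daily_csv

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pollutants = compute_indices(simulate_pollutants(config))
    weather = simulate_weather(config)
    eff_series = pollutants[config.effect.pollutant]
    chapter = simulate_counts(config, eff_series, weather)
    strata_counts = split_counts_by_strata(config, chapter)

    write_daily_csv(pollutants, outdir / "pollutants.csv")
    weather.rename_axis("date").to_csv(outdir / "weather.csv",
                                       date_format="%Y-%m-%d")
    counts_df = pd.concat({lbl: cs.data for lbl, cs in strata_counts.items()},
                          axis=1)
    counts_df.rename_axis("date").to_csv(outdir / "counts.csv",
                                         date_format="%Y-%m-%d")
    meta = {"rng": RNG_NAME, "seed": config.seed,
            "config": _config_to_jsonable(config),
            "planted": chapter.metadata}
    (outdir / "metadata.json").write_text(json.dumps(meta, indent=2))
    return meta


def _config_to_jsonable(config: SimulationConfig) -> dict:
    d = asdict(config)
    d["subgroup_proportions"] = {
        f"{sex}:{band}": v
        for (sex, band), v in config.subgroup_proportions.items()}
    return d
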