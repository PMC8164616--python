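import numpy as np
import pandas as pd
import pytest

import aircrossover as ac


@pytest.fixture(scope="session")
def base_config():
    """Six-month simulation spanning whole calendar months."""
    return ac.SimulationConfig(
        n_days=183, start_date="2004-04-01", seed=7,
        effect=ac.EffectParams("NO2", 1, 0.02))


@pytest.fixture(scope="session")
def simulated(base_config):
    pollutants = ac.compute_indices(ac.simulate_pollutants(base_config))
    weather = ac.simulate_weather(base_config)
    counts = ac.simulate_counts(base_config, pollutants["NO2"], weather)
    return pollutants, weather, counts


def minimal_config(seed, n_days=400, beta=0.0, lag=0, *, baseline=20.0,
                   month_sd=0.0, pollutant="NO2"):
    """Single-pollutant config for fast replicate loops."""
    return ac.SimulationConfig(
        n_days=n_days, start_date="2005-01-01", seed=seed,
        pollutant_params={pollutant: ac.PollutantParams(
            mean=20.0, amplitude=5.0, ar=0.5, sd=4.0)},
        effect=ac.EffectParams(pollutant, lag, beta),
        baseline_rate=baseline, month_effect_sd=month_sd)


def simulate_and_fit(cfg, spline_df=3):
    pol = ac.simulate_pollutants(cfg)
    weather = ac.simulate_weather(cfg)
    counts = ac.simulate_counts(cfg, pol[cfg.effect.pollutant], weather)
    ds = ac.build_dataset(counts, pol[cfg.effect.pollutant], weather,
                          cfg.effect.lag, spline_df=spline_df)
    return ac.fit_conditional_poisson(ds)
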