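"""YAML configuration loading for the command-line entry points."""

from __future__ import annotations

import yaml

from .pipeline import AnalysisConfig
from .simulate import (SimulationConfig, PollutantParams, WeatherParams,
                       EffectParams)


def simulation_config_from_dict(d: dict) -> SimulationConfig:
    d = dict(d)
    if "pollutant_params" in d:
        d["pollutant_params"] = {
            name: PollutantParams(**p)
            for name, p in d["pollutant_params"].items()}
    if "weather_params" in d:
        d["weather_params"] = WeatherParams(**d["weather_params"])
    if "effect" in d:
        d["effect"] = EffectParams(**d["effect"])
    if "subgroup_proportions" in d:
        d["subgroup_proportions"] = {
            tuple(k.split(":")): v
            for k, v in d["subgroup_proportions"].items()}
    if "dow_effects" in d:
        d["dow_effects"] = tuple(d["dow_effects"])
    return SimulationConfig(**d)


def analysis_config_from_dict(d: dict) -> AnalysisConfig:
    d = dict(d)
    if "simulation" in d and d["simulation"] is not None:
        d["simulation"] = simulation_config_from_dict(d["simulation"])
    for key in ("pollutants", "chapters", "lags", "p_thresholds"):
        if key in d:
            d[key] = tuple(d[key])
    return AnalysisConfig(**d)


def load_analysis_config(path) -> AnalysisConfig:
    with open(path) as fh:
        return analysis_config_from_dict(yaml.safe_load(fh))


def load_simulation_config(path) -> SimulationConfig:
    with open(path) as fh:
        return simulation_config_from_dict(yaml.safe_load(fh))
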