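"""Synthetic generator: determinism, planted structure, analytic means."""

import numpy as np
import pandas as pd
import pytest

import aircrossover as ac
from aircrossover.simulate import ConfigError
from conftest import minimal_config


def one_pollutant_config(seed=0, n_days=365, **pp):
    params = dict(mean=10.0, amplitude=0.0, ar=0.0, sd=0.0)
    params.update(pp)
    return ac.SimulationConfig(
        n_days=n_days, seed=seed,
        pollutant_params={"NO2": ac.PollutantParams(**params)})


class TestPollutants:
    def test_noise_free_constant_series(self):
        cfg = one_pollutant_config(mean=10.0)
        series = ac.simulate_pollutants(cfg)["NO2"]
        assert (series.values == 10.0).all()

    def test_same_seed_identical_different_seed_differs(self):
        a = ac.simulate_pollutants(one_pollutant_config(seed=1, sd=2.0))["NO2"]
        b = ac.simulate_pollutants(one_pollutant_config(seed=1, sd=2.0))["NO2"]
        c = ac.simulate_pollutants(one_pollutant_config(seed=2, sd=2.0))["NO2"]
        assert (a.values == b.values).all()
        assert not (a.values == c.values).all()

    def test_ar1_autocorrelation_recovered(self):
        # deseasonalised (amplitude 0) AR(1) with coefficient 0.6
        cfg = one_pollutant_config(n_days=10_000, mean=100.0, ar=0.6, sd=1.0)
        x = ac.simulate_pollutants(cfg)["NO2"].values
        xc = x - x.mean()
        acf1 = (xc[1:] @ xc[:-1]) / (xc @ xc)
        assert acf1 == pytest.approx(0.6, abs=0.05)

    def test_non_negative_everywhere(self):
        cfg = one_pollutant_config(n_days=3650, mean=1.0, ar=0.5, sd=3.0)
        assert (ac.simulate_pollutants(cfg)["NO2"].values >= 0).all()

    def test_missingness_injection(self):
        cfg = one_pollutant_config(n_days=2000, sd=1.0, missing_rate=0.1)
        vals = ac.simulate_pollutants(cfg)["NO2"].values
        frac = np.isnan(vals).mean()
        assert 0.05 < frac < 0.15

    def test_invalid_ar_rejected(self):
        with pytest.raises(ConfigError):
            ac.simulate_pollutants(one_pollutant_config(ar=1.0))

    def test_negative_sd_rejected(self):
        with pytest.raises(ConfigError):
            ac.simulate_pollutants(one_pollutant_config(sd=-1.0))


class TestWeather:
    def test_rh_mean_out_of_bounds_rejected(self):
        cfg = ac.SimulationConfig(
            weather_params=ac.WeatherParams(rh_mean=150.0))
        with pytest.raises(ConfigError):
            ac.simulate_weather(cfg)

    def test_noise_free_pure_sinusoid(self):
        cfg = ac.SimulationConfig(
            n_days=730, weather_params=ac.WeatherParams(
                temp_mean=10.0, temp_amplitude=12.0, temp_sd=0.0, rh_sd=0.0))
        w = ac.simulate_weather(cfg)
        assert w["temp"].max() - w["temp"].min() == pytest.approx(
            2 * 12.0, rel=1e-3)
        assert (w["rh"] == 70.0).all()

    def test_rh_always_in_bounds(self):
        cfg = ac.SimulationConfig(
            n_days=3650, seed=5,
            weather_params=ac.WeatherParams(rh_mean=90.0, rh_sd=30.0))
        rh = ac.simulate_weather(cfg)["rh"]
        assert rh.between(0.0, 100.0).all()


class TestCounts:
    def test_homogeneous_poisson_mean(self):
        # beta=0, flat dow, no weather/month effects: mean should be baseline
        cfg = minimal_config(seed=4, n_days=10_000, beta=0.0, baseline=20.0)
        pol = ac.simulate_pollutants(cfg)
        w = ac.simulate_weather(cfg)
        counts = ac.simulate_counts(cfg, pol["NO2"], w)
        tol = 3 * np.sqrt(20.0 / 10_000)
        assert counts.data.mean() == pytest.approx(20.0, abs=tol)

    def test_zero_baseline_rejected(self):
        with pytest.raises(ConfigError):
            minimal_config(seed=0, baseline=0.0).validate()

    def test_log_linear_rate_ratio(self):
        # constant exposure 10 vs 0 with beta=0.05: means differ by e^0.5
        means = []
        for level in (10.0, 0.0):
            cfg = ac.SimulationConfig(
                n_days=10_000, seed=9,
                pollutant_params={"NO2": ac.PollutantParams(
                    mean=level, amplitude=0.0, ar=0.0, sd=0.0)},
                effect=ac.EffectParams("NO2", 0, 0.05),
                baseline_rate=20.0, month_effect_sd=0.0)
            pol = ac.simulate_pollutants(cfg)
            w = ac.simulate_weather(cfg)
            means.append(ac.simulate_counts(cfg, pol["NO2"], w).data.mean())
        assert means[0] / means[1] == pytest.approx(np.exp(0.5), rel=0.03)

    def test_lagged_days_dropped_and_logged(self):
        cfg = minimal_config(seed=2, n_days=100, beta=0.01, lag=5)
        pol = ac.simulate_pollutants(cfg)
        w = ac.simulate_weather(cfg)
        counts = ac.simulate_counts(cfg, pol["NO2"], w)
        assert len(counts.data) == 95
        assert counts.metadata["n_days_dropped_missing_lag"] == 5

    def test_dow_effects_show_up(self):
        cfg = minimal_config(seed=3, n_days=7000, baseline=30.0)
        cfg.dow_effects = (2.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0)
        pol = ac.simulate_pollutants(cfg)
        w = ac.simulate_weather(cfg)
        counts = ac.simulate_counts(cfg, pol["NO2"], w)
        by_dow = counts.data.groupby(counts.data.index.weekday).mean()
        assert by_dow[0] / by_dow[1:].mean() == pytest.approx(2.0, rel=0.1)

    def test_n_days_too_short_rejected(self):
        with pytest.raises(ConfigError):
            ac.SimulationConfig(n_days=30).validate()


class TestStratumSplit:
    def test_subgroups_sum_to_all(self, base_config, simulated):
        _, _, counts = simulated
        strata = ac.split_counts_by_strata(base_config, counts)
        assert len(strata) == 18
        total = strata["Female"].data + strata["Male"].data
        pd.testing.assert_series_equal(total, strata["All"].data)
        ages = (strata["Age 0-10 all"].data + strata["Age 11-60 all"].data
                + strata["Age 60+ all"].data)
        pd.testing.assert_series_equal(ages, strata["All"].data)

    def test_season_strata_are_date_subsets(self, base_config, simulated):
        _, _, counts = simulated
        strata = ac.split_counts_by_strata(base_config, counts)
        warm = strata["Warm all"].data
        assert set(warm.index.month) <= {4, 5, 6, 7, 8, 9}
        n_all = len(strata["All"].data)
        assert len(warm) + len(strata["Cold all"].data) == n_all

    def test_split_is_deterministic(self, base_config, simulated):
        _, _, counts = simulated
        a = ac.split_counts_by_strata(base_config, counts)
        b = ac.split_counts_by_strata(base_config, counts)
        for lbl in a:
            assert (a[lbl].data == b[lbl].data).all()


class TestWriteSimulation:
    def test_outputs_and_metadata(self, tmp_path):
        cfg = ac.SimulationConfig(n_days=90, seed=11)
        meta = ac.write_simulation(cfg, tmp_path)
        for name in ("pollutants.csv", "weather.csv", "counts.csv",
                     "metadata.json"):
            assert (tmp_path / name).exists()
        assert meta["rng"].startswith("numpy PCG64")
        assert meta["planted"]["planted_beta"] == cfg.effect.beta
        counts = pd.read_csv(tmp_path / "counts.csv", index_col="date")
        assert counts.shape[1] == 18
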