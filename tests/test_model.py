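"""Natural splines, dataset assembly, and the conditional Poisson fit."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import aircrossover as ac
from aircrossover.model import (DataError, NotIdentifiedError, _cond_loglik,
                                natural_spline_basis)
from conftest import minimal_config, simulate_and_fit


class TestNaturalSplineBasis:
    def test_linear_beyond_boundary(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 10, 200)
        grid = np.linspace(12, 20, 50)  # entirely beyond the upper boundary
        basis = natural_spline_basis(grid, df=4,
                                     boundary_knots=(0, 10),
                                     interior_knots=np.quantile(x, [.25, .5, .75]))
        second_diff = np.diff(basis, n=2, axis=0)
        assert np.abs(second_diff).max() < 1e-8

    def test_df1_is_monotone_single_column(self):
        x = np.linspace(-3, 3, 50)
        basis = natural_spline_basis(x, df=1)
        assert basis.shape == (50, 1)
        assert (np.diff(basis[:, 0]) > 0).all()

    def test_linear_functions_in_span(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(-5, 5, 300)
        basis = natural_spline_basis(x, df=4)
        design = np.column_stack([np.ones_like(x), basis])
        coef, *_ = np.linalg.lstsq(design, x, rcond=None)
        assert np.abs(design @ coef - x).max() < 1e-8

    def test_columns_linearly_independent(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 1, 500)
        basis = natural_spline_basis(x, df=5)
        assert np.linalg.matrix_rank(basis) == 5

    def test_too_few_distinct_values_rejected(self):
        with pytest.raises(DataError):
            natural_spline_basis([1.0, 1.0, 2.0, 2.0], df=3)


class TestBuildDataset:
    def test_lag_14_row_count(self, base_config, simulated):
        pollutants, weather, counts = simulated
        ds = ac.build_dataset(counts, pollutants["NO2"], weather, lag=14)
        assert ds.n_rows == base_config.n_days - 14

    def test_zero_count_stratum_dropped(self, simulated):
        pollutants, weather, counts = simulated
        zeroed = counts.data.copy()
        keys = ac.build_time_strata(zeroed.index)
        target = keys.iloc[20]
        zeroed[(keys == target).to_numpy()] = 0
        cs = ac.CountSeries("X", "All", zeroed)
        ds = ac.build_dataset(cs, pollutants["NO2"], weather, lag=0)
        assert target not in ds.stratum_keys
        assert ds.n_dropped_strata >= 1

    def test_missing_exposure_drops_one_row(self, simulated):
        pollutants, weather, counts = simulated
        ds0 = ac.build_dataset(counts, pollutants["NO2"], weather, lag=0)
        holed = ac.ExposureSeries(
            "NO2", pollutants["NO2"].data.mask(
                pollutants["NO2"].data.index == pollutants["NO2"].data.index[50]))
        ds1 = ac.build_dataset(counts, holed, weather, lag=0)
        assert ds0.n_rows - ds1.n_rows == 1
        assert ds1.n_dropped_missing == 1

    def test_empty_dataset_errors(self, simulated):
        pollutants, weather, counts = simulated
        all_missing = ac.ExposureSeries(
            "NO2", pd.Series(np.nan, index=pollutants["NO2"].data.index))
        with pytest.raises(DataError):
            ac.build_dataset(counts, all_missing, weather, lag=0)


class TestConditionalPoissonFit:
    def fit_pair(self, seed, n_days=200, beta=0.02, spline_df=3):
        """Conditional fit and the statsmodels stratum-dummy oracle."""
        import statsmodels.api as sm
        cfg = minimal_config(seed, n_days=n_days, beta=beta, lag=1)
        pol = ac.simulate_pollutants(cfg)
        weather = ac.simulate_weather(cfg)
        counts = ac.simulate_counts(cfg, pol["NO2"], weather)
        ds = ac.build_dataset(counts, pol["NO2"], weather, 1,
                              spline_df=spline_df)
        res = ac.fit_conditional_poisson(ds)
        dummies = pd.get_dummies(pd.Series(ds.stratum_codes)).to_numpy(float)
        X = np.column_stack([ds.design(), dummies])
        glm = sm.GLM(ds.y, X, family=sm.families.Poisson()).fit()
        return res, glm

    @pytest.mark.parametrize("seed", [11, 12, 13])
    def test_equals_fixed_effects_poisson(self, seed):
        res, glm = self.fit_pair(seed)
        assert res.beta == pytest.approx(glm.params[0], rel=1e-6)
        assert res.se == pytest.approx(glm.bse[0], rel=1e-6)

    def test_stratum_constant_shift_leaves_beta_unchanged(self, simulated):
        pollutants, weather, counts = simulated
        ds = ac.build_dataset(counts, pollutants["NO2"], weather, lag=0)
        res0 = ac.fit_conditional_poisson(ds)
        # add a different constant to the exposure within every stratum
        shifts = np.linspace(-5, 5, ds.n_strata)
        ds.exposure = ds.exposure + shifts[ds.stratum_codes]
        res1 = ac.fit_conditional_poisson(ds)
        assert res1.beta == pytest.approx(res0.beta, abs=1e-7)

    def test_non_identified_exposure_rejected(self, simulated):
        pollutants, weather, counts = simulated
        ds = ac.build_dataset(counts, pollutants["NO2"], weather, lag=0)
        ds.exposure = np.ones(ds.n_rows)  # constant within every stratum
        with pytest.raises(NotIdentifiedError):
            ac.fit_conditional_poisson(ds)

    def test_result_metadata(self, simulated):
        pollutants, weather, counts = simulated
        ds = ac.build_dataset(counts, pollutants["NO2"], weather, lag=2)
        res = ac.fit_conditional_poisson(ds)
        assert res.converged
        assert res.se > 0
        assert 0 < res.p_value <= 1
        assert res.n_rows == ds.n_rows
        assert res.n_strata == ds.n_strata

    @settings(derandomize=True, max_examples=15, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_loglik_invariant_to_stratum_constants(self, seed):
        rng = np.random.default_rng(seed)
        n, S = 60, 6
        codes = np.sort(rng.integers(0, S, n))
        y = rng.poisson(5.0, n).astype(float)
        eta = rng.normal(0, 1, n)
        Y = np.bincount(codes, weights=y, minlength=S)
        ll0, _ = _cond_loglik(eta, y, codes, Y, S)
        shifts = rng.normal(0, 3, S)
        ll1, _ = _cond_loglik(eta + shifts[codes], y, codes, Y, S)
        assert ll1 == pytest.approx(ll0, rel=1e-9, abs=1e-7)


class TestWaldAndRR:
    def test_null_beta_gives_p_one(self):
        assert ac.wald_p(0.0, 1.0) == pytest.approx(1.0)

    @pytest.mark.parametrize("z,p", [(1.959964, 0.05), (3.290527, 0.001)])
    def test_normal_quantiles(self, z, p):
        assert ac.wald_p(z, 1.0) == pytest.approx(p, rel=1e-4)

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValueError):
            ac.wald_p(1.0, 0.0)

    def make_result(self, beta, se=0.01):
        return ac.ModelResult(beta=beta, se=se, p_value=ac.wald_p(beta, se),
                              n_rows=100, n_strata=10, converged=True,
                              iterations=5, log_likelihood=-1.0)

    def test_null_rr_is_one(self):
        rr = ac.relative_risk(self.make_result(0.0), increment=10)
        assert rr["rr"] == pytest.approx(1.0)
        assert rr["ci_low"] < 1.0 < rr["ci_high"]

    def test_rr_closed_form(self):
        rr = ac.relative_risk(self.make_result(0.001), increment=10)
        assert rr["rr"] == pytest.approx(np.exp(0.01))
        assert rr["rr"] == pytest.approx(1.01005, abs=1e-5)

    @settings(derandomize=True, max_examples=30)
    @given(beta=st.floats(-0.5, 0.5), se=st.floats(1e-4, 0.2),
           inc=st.floats(0.1, 50))
    def test_ci_contains_point_estimate(self, beta, se, inc):
        rr = ac.relative_risk(self.make_result(beta, se), increment=inc)
        assert rr["ci_low"] <= rr["rr"] <= rr["ci_high"]

    def test_nonconverged_rejected(self):
        res = self.make_result(0.1)
        res.converged = False
        with pytest.raises(ValueError):
            ac.relative_risk(res, increment=1.0)


class TestRecoverySmoke:
    def test_planted_beta_recovered(self):
        """A moderate planted slope lands within 2 SE across a few seeds."""
        hits = 0
        for seed in range(8):
            cfg = minimal_config(300 + seed, n_days=1200, beta=0.02, lag=3)
            res = simulate_and_fit(cfg)
            hits += abs(res.beta - 0.02) <= 2 * res.se
        assert hits >= 6
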