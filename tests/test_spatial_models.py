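"""Regression-suite tests: design helpers, weights, OLS oracle, spatial ML recovery."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from mobishift import (
    InputError,
    OLSRegression,
    SpatialErrorRegression,
    SpatialLagRegression,
    build_weights,
    distance_to_cbd,
    fit_ols,
    fit_spatial_error,
    fit_spatial_lag,
    model_comparison,
    standardize_predictors,
)
from mobishift.synthetic import CityConfig, generate_partitions


@pytest.fixture(scope="module")
def grid_weights():
    """Weights on a 20x20 grid (400 units), shared across ML tests."""
    cfg = CityConfig(grid_n=20, dzn_block=4, straddle_fraction=0.0, seed=2)
    origins, _ = generate_partitions(cfg)
    return build_weights(origins, k=8)


def _design(weights, rng, p=2):
    X = pd.DataFrame(
        rng.standard_normal((weights.n, p)),
        index=weights.ids,
        columns=[f"x{j}" for j in range(p)],
    )
    return X


def _lag_sample(weights, rng, rho, beta, sigma=0.2):
    X = _design(weights, rng, len(beta))
    eps = rng.normal(0, sigma, weights.n)
    eta = X.to_numpy() @ np.asarray(beta) + eps
    A = (sp.identity(weights.n) - rho * weights.W).tocsc()
    y = sp.linalg.spsolve(A, eta)
    return X, pd.Series(y, index=weights.ids)


def _error_sample(weights, rng, lam, beta, sigma=0.2):
    X = _design(weights, rng, len(beta))
    eps = rng.normal(0, sigma, weights.n)
    A = (sp.identity(weights.n) - lam * weights.W).tocsc()
    u = sp.linalg.spsolve(A, eps)
    y = pd.Series(X.to_numpy() @ np.asarray(beta) + u, index=weights.ids)
    return X, y


class TestDesignHelpers:
    def test_standardize_gives_zero_mean_unit_variance(self, rng):
        df = pd.DataFrame({"a": rng.normal(5, 3, 200), "b": rng.normal(-2, 0.5, 200)})
        z, means, sds = standardize_predictors(df)
        assert np.allclose(z.mean(), 0, atol=1e-12)
        assert np.allclose(z.std(ddof=0), 1, atol=1e-12)

    def test_already_standard_input_is_fixed_point(self, rng):
        x = rng.standard_normal(500)
        x = (x - x.mean()) / x.std(ddof=0)
        z, _, _ = standardize_predictors(pd.DataFrame({"a": x}))
        assert np.allclose(z["a"], x)

    def test_zero_variance_rejected(self):
        with pytest.raises(InputError, match="zero-variance"):
            standardize_predictors(pd.DataFrame({"a": np.ones(20)}))

    def test_raw_and_standardized_coefficients_related_by_sd(self, rng):
        df = pd.DataFrame({"a": rng.normal(0, 7, 300)})
        y = 2.0 * df["a"] + rng.normal(0, 0.1, 300)
        z, _, sds = standardize_predictors(df)
        r_raw = fit_ols(y, df)
        r_z = fit_ols(y, z)
        assert r_z.params["a"] == pytest.approx(r_raw.params["a"] * sds["a"], rel=1e-9)

    def test_distance_to_cbd(self):
        cfg = CityConfig(grid_n=4, dzn_block=2, straddle_fraction=0.0)
        origins, _ = generate_partitions(cfg)
        d0 = distance_to_cbd(origins, (0.5, 0.5))
        assert d0["o000c000"] == pytest.approx(0.0)
        d = distance_to_cbd(origins, (origins.centroids().loc["o000c000", "x"] - 3,
                                      origins.centroids().loc["o000c000", "y"] - 4))
        assert d["o000c000"] == pytest.approx(5.0)

    def test_distance_matches_bruteforce(self, grid_weights):
        cfg = CityConfig(grid_n=6, dzn_block=2, straddle_fraction=0.0)
        origins, _ = generate_partitions(cfg)
        cbd = (2.0, 3.0)
        d = distance_to_cbd(origins, cbd)
        cents = origins.centroids()
        for rid in origins.ids:
            expect = np.hypot(cents.loc[rid, "x"] - cbd[0], cents.loc[rid, "y"] - cbd[1])
            assert d[rid] == pytest.approx(expect)


class TestWeights:
    def test_three_collinear_points_k1(self):
        pts = pd.DataFrame({"x": [0.0, 1.0, 2.0], "y": [0.0, 0.0, 0.0]},
                           index=["a", "b", "c"])
        w = build_weights(pts, k=1)
        W = w.W.toarray()
        mid = list(w.ids).index("b")
        assert np.allclose(W[mid], [0.5, 0.0, 0.5])

    def test_rows_sum_to_one(self, grid_weights):
        sums = np.asarray(grid_weights.W.sum(axis=1)).ravel()
        assert np.allclose(sums, 1.0)
        assert grid_weights.W.diagonal().sum() == 0.0

    def test_interior_cell_k4_has_rook_neighbours(self):
        cfg = CityConfig(grid_n=5, dzn_block=5, straddle_fraction=0.0)
        origins, _ = generate_partitions(cfg)
        w = build_weights(origins, k=4)
        ids = list(w.ids)
        centre = ids.index("o002c002")
        nbrs = {ids[j] for j in w.W[centre].indices}
        assert nbrs == {"o001c002", "o003c002", "o002c001", "o002c003"}

    def test_spectrum_is_real_and_bounded(self, grid_weights):
        eigs = grid_weights.eigenvalues()
        assert eigs.max() == pytest.approx(1.0, abs=1e-10)
        assert eigs.min() >= -1.0 - 1e-10

    def test_too_few_units_rejected(self):
        pts = pd.DataFrame({"x": [0.0, 1.0], "y": [0.0, 0.0]}, index=["a", "b"])
        with pytest.raises(InputError):
            build_weights(pts, k=8)


class TestOls:
    def test_noiseless_line_recovered_exactly(self):
        x = np.linspace(-3, 3, 50)
        res = fit_ols(pd.Series(2 * x), pd.DataFrame({"x": x}))
        assert res.params["x"] == pytest.approx(2.0, abs=1e-12)
        assert res.params["intercept"] == pytest.approx(0.0, abs=1e-12)

    def test_independent_outcome_gives_null_coefficients(self, rng):
        X = pd.DataFrame(rng.standard_normal((4000, 2)), columns=["a", "b"])
        y = pd.Series(rng.standard_normal(4000))
        res = fit_ols(y, X)
        assert abs(res.params["a"]) < 0.06 and abs(res.params["b"]) < 0.06
        assert res.pvalues["a"] > 0.001

    def test_matches_normal_equations_oracle(self, rng):
        X = pd.DataFrame(rng.standard_normal((200, 3)), columns=list("abc"))
        y = pd.Series(X["a"] - 0.5 * X["c"] + rng.normal(0, 0.3, 200))
        res = fit_ols(y, X)
        Z = np.column_stack([np.ones(200), X.to_numpy()])
        beta = np.linalg.solve(Z.T @ Z, Z.T @ y.to_numpy())
        assert np.allclose(res.params.to_numpy(), beta, atol=1e-10)

    def test_rank_deficient_design_rejected(self, rng):
        x = rng.standard_normal(50)
        X = pd.DataFrame({"a": x, "b": 2 * x})
        with pytest.raises(InputError, match="rank"):
            fit_ols(pd.Series(x), X)

    def test_sklearn_estimator_protocol(self, rng):
        X = pd.DataFrame(rng.standard_normal((100, 2)), columns=["a", "b"])
        y = pd.Series(X["a"] * 3 + 1)
        est = OLSRegression().fit(X, y)
        assert est.get_params()["model_name"] == "ols"
        assert np.allclose(est.predict(X), y, atol=1e-9)


class TestSpatialLag:
    def test_zero_rho_data_recovers_zero(self, grid_weights, rng):
        X, y = _lag_sample(grid_weights, rng, rho=0.0, beta=[-0.1, 0.0])
        res = fit_spatial_lag(y, X, grid_weights)
        assert abs(res.rho_lag) < 0.1

    def test_joint_recovery_rho_and_beta(self, grid_weights):
        rhos, betas = [], []
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            X, y = _lag_sample(grid_weights, rng, rho=0.5, beta=[-0.1, 0.0])
            res = fit_spatial_lag(y, X, grid_weights)
            rhos.append(res.rho_lag)
            betas.append(res.params["x0"])
        assert np.mean(rhos) == pytest.approx(0.5, abs=0.05)
        assert np.mean(betas) == pytest.approx(-0.1, abs=0.02)

    def test_reduces_to_ols_at_zero(self, grid_weights, rng):
        """Concentrated lag likelihood at rho=0 equals the OLS ML likelihood."""
        X, y = _lag_sample(grid_weights, rng, rho=0.4, beta=[0.2, -0.3])
        ols = fit_ols(y, X)
        n = grid_weights.n
        Z = np.column_stack([np.ones(n), X.to_numpy()])
        resid = y.to_numpy() - Z @ np.linalg.lstsq(Z, y.to_numpy(), rcond=None)[0]
        sse = resid @ resid
        ll0 = -n / 2 * (np.log(2 * np.pi * sse / n) + 1)  # logdet term vanishes at rho=0
        assert ll0 == pytest.approx(ols.loglik, rel=1e-12)

    def test_significant_rho_has_small_pvalue(self, grid_weights, rng):
        X, y = _lag_sample(grid_weights, rng, rho=0.6, beta=[0.3, 0.0])
        res = fit_spatial_lag(y, X, grid_weights)
        assert res.pvalues["rho_lag"] < 1e-4


class TestSpatialError:
    def test_zero_lambda_data_matches_ols(self, grid_weights, rng):
        X, y = _error_sample(grid_weights, rng, lam=0.0, beta=[-0.1, 0.0])
        res = fit_spatial_error(y, X, grid_weights)
        ols = fit_ols(y, X)
        assert abs(res.lambda_err) < 0.15
        assert res.params["x0"] == pytest.approx(ols.params["x0"], abs=0.01)

    def test_lambda_recovery(self, grid_weights):
        lams = []
        for seed in range(5):
            rng = np.random.default_rng(200 + seed)
            X, y = _error_sample(grid_weights, rng, lam=0.5, beta=[-0.1, 0.0])
            lams.append(fit_spatial_error(y, X, grid_weights).lambda_err)
        assert np.mean(lams) == pytest.approx(0.5, abs=0.07)

    def test_likelihood_at_zero_equals_ols(self, grid_weights, rng):
        X, y = _error_sample(grid_weights, rng, lam=0.3, beta=[0.1, 0.2])
        est = SpatialErrorRegression(weights=grid_weights).fit(X, y)
        ols = fit_ols(y, X)
        # evaluate the error-model likelihood with the spatial parameter pinned at 0
        n = grid_weights.n
        Z = np.column_stack([np.ones(n), X.to_numpy()])
        beta0 = np.linalg.lstsq(Z, y.to_numpy(), rcond=None)[0]
        resid = y.to_numpy() - Z @ beta0
        s2 = resid @ resid / n
        ll0 = -n / 2 * (np.log(2 * np.pi * s2) + 1)
        assert ll0 == pytest.approx(ols.loglik, rel=1e-12)
        assert est.loglik_ >= ll0  # ML at the optimum dominates the rho=0 profile


class TestModelComparison:
    def test_identical_models_have_zero_delta(self, rng):
        X = pd.DataFrame(rng.standard_normal((100, 2)), columns=["a", "b"])
        y = pd.Series(X["a"] + rng.normal(0, 0.5, 100))
        r1, r2 = fit_ols(y, X), fit_ols(y, X)
        cmp_df = model_comparison([r1, r2])
        assert (cmp_df["delta_aic"] == 0).all()

    def test_mismatched_units_rejected(self, rng):
        X1 = pd.DataFrame(rng.standard_normal((100, 2)), columns=["a", "b"])
        X2 = pd.DataFrame(rng.standard_normal((90, 2)), columns=["a", "b"])
        r1 = fit_ols(pd.Series(rng.standard_normal(100)), X1)
        r2 = fit_ols(pd.Series(rng.standard_normal(90)), X2)
        with pytest.raises(InputError, match="identical"):
            model_comparison([r1, r2])

    def test_pure_noise_predictor_costs_about_two_aic(self, rng):
        X = pd.DataFrame(rng.standard_normal((2000, 1)), columns=["a"])
        y = pd.Series(X["a"] * 0.5 + rng.normal(0, 1, 2000))
        Xn = X.copy()
        Xn["noise"] = rng.standard_normal(2000)
        r_small, r_big = fit_ols(y, X), fit_ols(y, Xn)
        # AIC penalty 2 minus the (chi2_1-distributed) likelihood gain
        delta = r_big.aic - r_small.aic
        assert -8 < delta <= 2.01

    def test_nested_lag_on_independent_data(self, grid_weights, rng):
        X, y = _lag_sample(grid_weights, rng, rho=0.0, beta=[0.2, 0.0])
        r_ols = fit_ols(y, X)
        r_lag = fit_spatial_lag(y, X, grid_weights)
        assert r_lag.aic - r_ols.aic <= 2.5  # typically within +2 of each other
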