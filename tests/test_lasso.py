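"""Fixed-effects LASSO core: KKT conditions, closed forms, external oracles."""

import numpy as np
import pytest
import statsmodels.api as sm
from sklearn.linear_model import ElasticNet, LogisticRegression

from clusterlasso.lasso import (
    SeparationError,
    fit_at_lambda,
    fit_path,
    full_coef_vector,
    kkt_violation,
    lambda_max_fixed,
    penalized_objective,
    post_lasso_refit,
    predict,
)
from tests.conftest import enet_oracle_polished, make_dataset, random_instance


# ---------------------------------------------------------------------------
# stationarity and objective optimality
# ---------------------------------------------------------------------------

class TestOptimality:
    @pytest.mark.parametrize("family", ["gaussian", "binomial"])
    @pytest.mark.parametrize("alpha", [1.0, 0.99999, 0.7])
    def test_kkt_and_oracle_objective(self, family, alpha):
        rng = np.random.default_rng(hash((family, alpha)) % 2**31)
        for _ in range(8):
            n, p = int(rng.integers(25, 60)), int(rng.integers(2, 9))
            data = random_instance(rng, n, p, family=family)
            lam = float(10 ** rng.uniform(-3, -0.7))
            fit = fit_at_lambda(data, lam, alpha=alpha)
            assert kkt_violation(data, fit) <= 1e-6
            oracle = enet_oracle_polished(data.X, data.y, lam, alpha, family)
            assert abs(penalized_objective(data, fit) - oracle) <= 1e-8

    def test_kkt_holds_with_cluster_dummies(self):
        rng = np.random.default_rng(7)
        data = random_instance(rng, 120, 5, family="gaussian", n_clusters=6)
        fit = fit_at_lambda(data, 0.05, include_cluster_dummies=True)
        assert kkt_violation(data, fit) <= 1e-6


# ---------------------------------------------------------------------------
# closed-form limits
# ---------------------------------------------------------------------------

class TestClosedForms:
    def test_null_model_at_and_above_lambda_max(self):
        rng = np.random.default_rng(11)
        data = random_instance(rng, 80, 6)
        lam_max = lambda_max_fixed(data)
        for lam in (lam_max, 1.3 * lam_max):
            fit = fit_at_lambda(data, lam)
            assert fit.n_selected == 0
            np.testing.assert_allclose(fit.intercept, data.y.mean(), rtol=1e-12)

    def test_just_below_lambda_max_selects(self):
        rng = np.random.default_rng(12)
        data = random_instance(rng, 80, 6)
        lam_max = lambda_max_fixed(data)
        assert fit_at_lambda(data, 0.98 * lam_max).n_selected >= 1

    def test_orthonormal_design_soft_threshold(self):
        # columns orthogonal to each other and to the constant, x_j'x_j = n:
        # the lasso solution is soft(x_j'y / n, lam) exactly
        rng = np.random.default_rng(13)
        n, p = 64, 5
        M = np.column_stack([np.ones(n), rng.standard_normal((n, p))])
        Q, _ = np.linalg.qr(M)
        X = Q[:, 1:] * np.sqrt(n)
        y = rng.standard_normal(n) + X @ np.array([1.0, -0.5, 0.2, 0.0, 0.0])
        data = make_dataset(X, y)
        lam = 0.15
        fit = fit_at_lambda(data, lam, alpha=1.0)
        z = X.T @ (y - y.mean()) / n
        expected = np.sign(z) * np.maximum(np.abs(z) - lam, 0.0)
        np.testing.assert_allclose(fit.beta, expected, atol=1e-8)
        np.testing.assert_allclose(fit.intercept, y.mean(), atol=1e-8)

    def test_lambda_zero_gaussian_matches_ols(self):
        rng = np.random.default_rng(14)
        data = random_instance(rng, 90, 6)
        fit = fit_at_lambda(data, 0.0)
        ols = sm.OLS(data.y, sm.add_constant(data.X)).fit()
        np.testing.assert_allclose(fit.intercept, ols.params[0], atol=1e-6)
        np.testing.assert_allclose(fit.beta, ols.params[1:], atol=1e-6)

    def test_lambda_zero_binomial_matches_logit_mle(self):
        rng = np.random.default_rng(15)
        data = random_instance(rng, 300, 4, family="binomial")
        fit = fit_at_lambda(data, 0.0)
        mle = sm.Logit(data.y, sm.add_constant(data.X)).fit(disp=0)
        np.testing.assert_allclose(fit.intercept, mle.params[0], atol=1e-6)
        np.testing.assert_allclose(fit.beta, mle.params[1:], atol=1e-6)

    def test_separation_raises_at_lambda_zero(self):
        X = np.linspace(-2, 2, 40).reshape(-1, 1)
        y = (X[:, 0] > 0).astype(float)  # perfectly separable
        data = make_dataset(X / X.std(), y, family="binomial")
        with pytest.raises(SeparationError):
            fit_at_lambda(data, 0.0)


# ---------------------------------------------------------------------------
# cross-checks against scikit-learn solvers
# ---------------------------------------------------------------------------

class TestSklearnCrossChecks:
    def test_gaussian_elastic_net_matches_sklearn(self):
        rng = np.random.default_rng(16)
        data = random_instance(rng, 150, 8)
        for lam, l1_ratio in [(0.05, 1.0), (0.1, 0.6)]:
            ours = fit_at_lambda(data, lam, alpha=l1_ratio)
            ref = ElasticNet(
                alpha=lam, l1_ratio=l1_ratio, fit_intercept=True,
                tol=1e-10, max_iter=100000,
            ).fit(data.X, data.y)
            np.testing.assert_allclose(ours.beta, ref.coef_, atol=1e-6)
            np.testing.assert_allclose(ours.intercept, ref.intercept_, atol=1e-6)

    def test_binomial_l1_matches_sklearn_saga(self):
        rng = np.random.default_rng(17)
        data = random_instance(rng, 400, 5, family="binomial")
        lam = 0.02
        ours = fit_at_lambda(data, lam, alpha=1.0)
        ref = LogisticRegression(
            C=1.0 / (data.n * lam), l1_ratio=1.0, solver="saga",
            tol=1e-10, max_iter=100000,
        ).fit(data.X, data.y)
        np.testing.assert_allclose(ours.beta, ref.coef_[0], atol=1e-5)
        np.testing.assert_allclose(ours.intercept, ref.intercept_[0], atol=1e-5)


# ---------------------------------------------------------------------------
# path, refit, prediction, bookkeeping
# ---------------------------------------------------------------------------

class TestPathAndRefit:
    def test_path_shapes_and_tables(self):
        rng = np.random.default_rng(18)
        data = random_instance(rng, 100, 6)
        lam_max = lambda_max_fixed(data)
        lambdas = 1.05 * lam_max * (0.001 ** (np.arange(20) / 19))
        path = fit_path(data, lambdas)
        assert len(path.fits) == 20
        table = path.table()
        assert list(table["lambda"]) == list(lambdas)
        assert table["n_selected"].iloc[0] == 0
        assert table["n_selected"].iloc[-1] >= 1
        coefs = path.coef_table()
        assert coefs.shape == (20, 6)

    def test_warm_path_matches_cold_fits(self):
        rng = np.random.default_rng(19)
        data = random_instance(rng, 90, 5)
        lam_max = lambda_max_fixed(data)
        lambdas = lam_max * (0.01 ** (np.arange(10) / 9))
        path = fit_path(data, lambdas)
        for lam, warm in zip(lambdas[5:], path.fits[5:]):
            cold = fit_at_lambda(data, lam)
            np.testing.assert_allclose(warm.beta, cold.beta, atol=1e-6)

    def test_post_refit_is_ols_on_support(self):
        rng = np.random.default_rng(20)
        data = random_instance(rng, 120, 8)
        fit = fit_at_lambda(data, 0.08)
        assert 0 < fit.n_selected < 8
        refit = post_lasso_refit(data, fit)
        assert refit.estimator == "post"
        np.testing.assert_array_equal(refit.support, fit.support)
        active = fit.support
        ols = sm.OLS(data.y, sm.add_constant(data.X[:, active])).fit()
        np.testing.assert_allclose(refit.beta[active], ols.params[1:], atol=1e-6)
        assert np.all(refit.beta[np.setdiff1d(np.arange(8), active)] == 0)

    def test_dummy_variant_reference_coding(self):
        rng = np.random.default_rng(21)
        data = random_instance(rng, 150, 4, n_clusters=5)
        fit = fit_at_lambda(data, 0.02, include_cluster_dummies=True)
        assert fit.cluster_kind == "dummy"
        # first sorted hospital is the reference with effect exactly 0
        assert fit.cluster_effects[0] == 0.0
        assert len(fit.cluster_effects) == data.n_clusters
        assert len(full_coef_vector(fit)) == data.p + data.n_clusters - 1

    def test_predict_applies_cluster_effects(self):
        rng = np.random.default_rng(22)
        data = random_instance(rng, 150, 4, n_clusters=5)
        fit = fit_at_lambda(data, 0.02, include_cluster_dummies=True)
        pred = predict(fit, data.X, data.cluster)
        pos = np.searchsorted(fit.cluster_labels, data.cluster)
        manual = fit.intercept + data.X @ fit.beta + fit.cluster_effects[pos]
        np.testing.assert_allclose(pred, manual)

    def test_predict_unknown_hospital_raises(self):
        rng = np.random.default_rng(23)
        data = random_instance(rng, 100, 3, n_clusters=4)
        fit = fit_at_lambda(data, 0.02, include_cluster_dummies=True)
        with pytest.raises(KeyError):
            predict(fit, data.X[:2], np.array([999, 999]))

    def test_information_criteria_formulas(self):
        rng = np.random.default_rng(24)
        data = random_instance(rng, 80, 5)
        fit = fit_at_lambda(data, 0.05)
        assert fit.df == fit.n_selected + 1
        np.testing.assert_allclose(fit.aic, -2 * fit.loglik + 2 * fit.df)
        np.testing.assert_allclose(
            fit.bic, -2 * fit.loglik + np.log(data.n) * fit.df
        )

    def test_invalid_arguments(self):
        rng = np.random.default_rng(25)
        data = random_instance(rng, 30, 2)
        with pytest.raises(ValueError):
            fit_at_lambda(data, -0.1)
        with pytest.raises(ValueError):
            fit_at_lambda(data, 0.1, alpha=0.0)
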