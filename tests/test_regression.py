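import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pminr import (
    DesignSpec,
    NetworkTopology,
    SampleData,
    build_design,
    fit_logistic,
    fit_pminr,
    lrt_global,
    pmnr_features,
    wald_tests,
)
from pminr.regression import SeparationWarning


def _sample_data(rng, topology, n=200, sigma=None):
    p = topology.n_nodes
    sigma = np.eye(p) if sigma is None else sigma
    X = rng.multivariate_normal(np.zeros(p), sigma, size=n)
    y = rng.integers(0, 2, size=n)
    return SampleData(X=pd.DataFrame(X, columns=list(topology.node_names)), y=y)


def newton_logistic(design, y, tol=1e-12, iters=200):
    """Plain Newton-Raphson logistic MLE, kept independent of the package path."""
    beta = np.zeros(design.shape[1])
    for _ in range(iters):
        mu = 1.0 / (1.0 + np.exp(-design @ beta))
        grad = design.T @ (y - mu)
        hess = design.T @ (design * (mu * (1 - mu))[:, None])
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.abs(step).max() < tol:
            break
    return beta


class TestPmnrFeatures:
    def test_column_mean_is_pearson_r(self, rng, tiny_topology):
        X = rng.multivariate_normal(np.zeros(4), np.eye(4) * 2.0, size=150)
        feats = pmnr_features(X, tiny_topology)
        n = X.shape[0]
        for c, (i, j) in enumerate(feats.edge_index):
            r = stats.pearsonr(X[:, i], X[:, j]).statistic
            assert feats.values[:, c].mean() == pytest.approx(r * (n - 1) / n)

    def test_independent_nodes_mean_near_zero(self, rng, tiny_topology):
        X = rng.standard_normal((2000, 4))
        feats = pmnr_features(X, tiny_topology)
        assert np.abs(feats.values.mean(axis=0)).max() < 0.05

    def test_identical_columns_give_squared_zscores(self, rng, tiny_topology):
        X = rng.standard_normal((80, 4))
        X[:, 1] = X[:, 0]
        feats = pmnr_features(X, tiny_topology)
        z = (X[:, 0] - X[:, 0].mean()) / X[:, 0].std(ddof=1)
        np.testing.assert_allclose(feats.values[:, 0], z**2, rtol=1e-10)
        assert feats.values[:, 0].mean() == pytest.approx(79 / 80)

    def test_degenerate_node_rejected(self, rng, tiny_topology):
        X = rng.standard_normal((60, 4))
        X[:, 0] = 3.0
        with pytest.raises(ValueError, match="A"):
            pmnr_features(X, tiny_topology)


class TestBuildDesign:
    def test_column_count_full_fixture(self, rng, fixture_topology):
        data = _sample_data(rng, fixture_topology, n=120)
        feats = pmnr_features(data.node_matrix(fixture_topology), fixture_topology)
        design, spec = build_design(data, fixture_topology, feats)
        assert design.shape[1] == 1 + 26 + 37 == spec.n_columns
        assert spec.roles[0] == "intercept"
        assert spec.roles.count("node") == 26
        assert spec.roles.count("edge") == 37

    def test_empty_edge_set(self, rng):
        topo = NetworkTopology(("A", "B", "C"))
        data = _sample_data(rng, topo, n=50)
        feats = pmnr_features(data.node_matrix(topo), topo)
        design, spec = build_design(data, topo, feats)
        assert design.shape[1] == 1 + 3
        assert spec.edge_names == ()

    def test_non_binary_response_rejected(self, rng, tiny_topology):
        X = pd.DataFrame(rng.standard_normal((30, 4)), columns=list("ABCD"))
        with pytest.raises(ValueError, match="binary"):
            SampleData(X=X, y=np.array([0, 1, 2] * 10))

    def test_mismatched_rows_rejected(self, rng, tiny_topology):
        data = _sample_data(rng, tiny_topology, n=60)
        feats = pmnr_features(
            rng.standard_normal((50, 4)), tiny_topology
        )
        with pytest.raises(ValueError, match="rows"):
            build_design(data, tiny_topology, feats)

    def test_covariates_enter_between_intercept_and_nodes(self, rng, tiny_topology):
        data = _sample_data(rng, tiny_topology, n=60)
        Z = pd.DataFrame({"age": rng.standard_normal(60)})
        data = SampleData(X=data.X, y=data.y, Z=Z)
        feats = pmnr_features(data.node_matrix(tiny_topology), tiny_topology)
        _, spec = build_design(data, tiny_topology, feats)
        assert spec.term_names[1] == "age"
        assert spec.roles[1] == "covariate"


class TestFitLogistic:
    def test_intercept_only_balanced(self):
        design = np.ones((40, 1))
        y = np.array([0.0, 1.0] * 20)
        fit = fit_logistic(design, y, DesignSpec((), (), ()))
        assert fit.coefficients[0] == pytest.approx(0.0, abs=1e-10)
        assert fit.converged

    def test_matches_newton_oracle_fixed_dataset(self):
        rng = np.random.default_rng(5)
        design = np.column_stack([np.ones(20), rng.standard_normal((20, 2))])
        y = (rng.random(20) < 0.5).astype(float)
        fit = fit_logistic(design, y)
        np.testing.assert_allclose(
            fit.coefficients, newton_logistic(design, y), atol=1e-6
        )

    def test_matches_oracle_on_random_small_problems(self):
        rng = np.random.default_rng(99)
        for _ in range(10):
            n = 200
            design = np.column_stack([np.ones(n), rng.standard_normal((n, 6))])
            truth = rng.uniform(-0.5, 0.5, size=7)
            y = (rng.random(n) < 1 / (1 + np.exp(-design @ truth))).astype(float)
            fit = fit_logistic(design, y)
            assert fit.converged
            np.testing.assert_allclose(
                fit.coefficients, newton_logistic(design, y), atol=1e-5
            )

    def test_covariance_is_inverse_information(self):
        rng = np.random.default_rng(3)
        design = np.column_stack([np.ones(300), rng.standard_normal((300, 2))])
        y = (rng.random(300) < 0.5).astype(float)
        fit = fit_logistic(design, y)
        mu = 1.0 / (1.0 + np.exp(-design @ fit.coefficients))
        info = design.T @ (design * (mu * (1 - mu))[:, None])
        np.testing.assert_allclose(fit.covariance, np.linalg.inv(info), rtol=1e-6)

    def test_perfect_separation_flagged(self):
        x = np.linspace(-2, 2, 50)
        design = np.column_stack([np.ones(50), x])
        y = (x > 0).astype(float)
        with pytest.warns(SeparationWarning):
            fit = fit_logistic(design, y)
        assert not fit.converged

    def test_duplicated_column_raises_collinearity(self, rng):
        x = rng.standard_normal(100)
        design = np.column_stack([np.ones(100), x, x])
        y = (rng.random(100) < 0.5).astype(float)
        with pytest.raises(np.linalg.LinAlgError, match="collinear"):
            fit_logistic(design, y)

    def test_row_permutation_invariance(self, rng):
        n = 150
        design = np.column_stack([np.ones(n), rng.standard_normal((n, 3))])
        y = (rng.random(n) < 0.5).astype(float)
        fit = fit_logistic(design, y)
        perm = rng.permutation(n)
        fit2 = fit_logistic(design[perm], y[perm])
        np.testing.assert_allclose(fit.coefficients, fit2.coefficients, atol=1e-8)
        assert fit.loglik == pytest.approx(fit2.loglik)


class TestWaldAndLrt:
    def test_two_sided_normal_tail(self):
        fit = _fake_fit(np.array([0.0, 1.959964]), np.eye(2))
        table = wald_tests(fit)
        assert table["p"].iloc[0] == pytest.approx(1.0)
        assert table["p"].iloc[1] == pytest.approx(0.05, abs=1e-6)

    def test_p_monotone_in_abs_z(self):
        fit = _fake_fit(np.array([0.5, 1.0, 2.0, 3.0]), np.eye(4))
        p = wald_tests(fit)["p"].to_numpy()
        assert (np.diff(p) < 0).all()

    def test_lrt_zero_for_empty_network(self, rng):
        topo = NetworkTopology(("A",), frozenset())
        # network df counts nodes + edges; an empty spec reduces to identity
        data = _sample_data(rng, topo, n=60)
        fit = fit_logistic(np.ones((60, 1)), data.y, DesignSpec((), (), ()))
        stat, df, p = lrt_global(fit, data)
        assert (stat, df, p) == (0.0, 0, 1.0)

    def test_lrt_df_counts_nodes_plus_edges(self, rng, fixture_topology):
        data = _sample_data(rng, fixture_topology, n=400)
        fit = fit_pminr(data, fixture_topology, method="product")
        assert fit.lrt_df == 26 + 37
        assert fit.lrt_statistic >= 0
        assert 0 <= fit.lrt_p <= 1

    def test_lrt_nonnegative_on_nested_fits(self, rng, tiny_topology):
        for seed in range(5):
            r = np.random.default_rng(seed)
            data = _sample_data(r, tiny_topology, n=120)
            fit = fit_pminr(data, tiny_topology, method="product")
            assert fit.lrt_statistic >= 0


def _fake_fit(coef, cov):
    from pminr.regression import NetworkRegressionFit

    spec = DesignSpec((), tuple(f"x{i}" for i in range(len(coef))), (), intercept=False)
    return NetworkRegressionFit(
        spec=spec, coefficients=coef, covariance=cov,
        loglik=0.0, converged=True, n_obs=0, n_iter=1,
    )


class TestFitPminr:
    def test_unknown_method_rejected(self, rng, tiny_topology):
        data = _sample_data(rng, tiny_topology, n=60)
        with pytest.raises(ValueError, match="unknown method"):
            fit_pminr(data, tiny_topology, method="spearman")

    def test_matches_statsmodels_logit(self, rng, tiny_topology):
        import statsmodels.api as sm

        data = _sample_data(rng, tiny_topology, n=300)
        fit = fit_pminr(data, tiny_topology, method="product")
        feats = pmnr_features(data.node_matrix(tiny_topology), tiny_topology)
        design, _ = build_design(data, tiny_topology, feats)
        ref = sm.Logit(data.y, design).fit(disp=0)
        np.testing.assert_allclose(fit.coefficients, ref.params, atol=1e-5)
        np.testing.assert_allclose(fit.loglik, ref.llf, atol=1e-6)

    def test_node_pvalues_concordant_across_methods(self, fixture_topology):
        from pminr import sample_covariance

        rng = np.random.default_rng(77)
        sigma = sample_covariance(fixture_topology, rng)
        n = 600
        X = rng.multivariate_normal(np.zeros(26), sigma, size=n)
        eta = 0.4 * X[:, 3]
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        data = SampleData(
            X=pd.DataFrame(X, columns=list(fixture_topology.node_names)), y=y
        )
        p_pmi = fit_pminr(data, fixture_topology, method="pmi").wald.query(
            "role == 'node'")["p"].to_numpy()
        p_prod = fit_pminr(data, fixture_topology, method="product").wald.query(
            "role == 'node'")["p"].to_numpy()
        rho = stats.spearmanr(p_pmi, p_prod).statistic
        assert rho > 0.8

    def test_bonferroni_column_bounded(self, rng, tiny_topology):
        data = _sample_data(rng, tiny_topology, n=100)
        fit = fit_pminr(data, tiny_topology, method="product", bonferroni=True)
        table = fit.summary_frame(bonferroni=True)
        assert (table["p_bonferroni"] <= 1.0).all()
        assert (table["p_bonferroni"] >= table["p"] - 1e-15).all()
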