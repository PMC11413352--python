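"""Undirected-network estimation: standardization, glasso, EBIC, bootstrap."""

import numpy as np
import pytest
from sklearn.covariance import graphical_lasso as sk_glasso

import eapnet as e
from eapnet.ggm import ConvergenceError, _lambda_path, _glasso_path_kernel, kkt_residual

from oracles import admm_glasso, glasso_objective


class TestStandardize:
    def test_symmetric_three_point(self):
        out = e.standardize(np.array([[1.0, 4.0], [2.0, 5.0], [3.0, 6.0]]))
        assert np.allclose(out.values[:, 0], [-1, 0, 1])

    def test_idempotent(self, rng):
        X = rng.normal(size=(50, 4))
        once = e.standardize(X)
        twice = e.standardize(once)
        assert np.abs(once.values - twice.values).max() < 1e-12

    def test_constant_column_rejected(self):
        with pytest.raises(ValueError, match="V1"):
            e.standardize(np.array([[1.0, 2.0], [2.0, 2.0], [3.0, 2.0]]))

    def test_missing_values_rejected(self):
        X = np.array([[1.0, np.nan], [2.0, 3.0], [0.0, 1.0]])
        with pytest.raises(ValueError, match="missing"):
            e.standardize(X)

    def test_moments(self, rng):
        out = e.standardize(rng.normal(2.0, 5.0, size=(200, 3)))
        assert np.abs(out.values.mean(axis=0)).max() < 1e-10
        assert np.abs(out.values.std(axis=0, ddof=1) - 1).max() < 1e-10


class TestCorrelationNetworks:
    def test_duplicated_column_correlates_fully(self, rng):
        x = rng.normal(size=100)
        R = e.pearson_network(e.standardize(np.column_stack([x, x + 0.0, rng.normal(size=100)])))
        assert R[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_matches_hand_formula_small_table(self):
        X = np.array([[1.0, 2.0], [2.0, 1.0], [3.0, 5.0], [4.0, 3.0], [5.0, 6.0]])
        xc = X - X.mean(axis=0)
        hand = float(
            (xc[:, 0] * xc[:, 1]).sum()
            / np.sqrt((xc[:, 0] ** 2).sum() * (xc[:, 1] ** 2).sum())
        )
        R = e.pearson_network(e.standardize(X))
        assert R[0, 1] == pytest.approx(hand, abs=1e-12)

    def test_independent_columns_near_zero(self, rng):
        X = rng.normal(size=(100_000, 4))
        R = e.pearson_network(e.standardize(X))
        assert np.abs(R - np.eye(4)).max() < 0.02

    def test_partial_corr_two_variables_equals_pearson(self, rng):
        X = rng.normal(size=(200, 2))
        X[:, 1] += 0.5 * X[:, 0]
        std = e.standardize(X)
        assert e.unregularized_partial_corr(std)[0, 1] == pytest.approx(
            e.pearson_network(std)[0, 1], abs=1e-10
        )

    def test_partial_corr_chain_vanishes(self, rng):
        n = 100_000
        a = rng.normal(size=n)
        b = 0.6 * a + rng.normal(size=n) * 0.8
        c = 0.6 * b + rng.normal(size=n) * 0.8
        pc = e.unregularized_partial_corr(e.standardize(np.column_stack([a, b, c])))
        assert abs(pc[0, 2]) < 0.02

    def test_identity_correlation_gives_zero_partials(self):
        # columns orthogonal to each other and to the constant vector
        # => exactly diagonal correlation matrix
        G = np.random.default_rng(0).normal(size=(40, 5))
        G[:, 0] = 1.0
        Q = np.linalg.qr(G)[0]
        pc = e.unregularized_partial_corr(e.standardize(Q[:, 1:]))
        assert np.abs(pc - np.eye(4)).max() < 1e-8


class TestGlassoSolver:
    def _random_corr(self, rng, p, n=200):
        X = rng.normal(size=(n, p)) @ (np.eye(p) + 0.3 * rng.normal(size=(p, p)))
        S = np.corrcoef(X.T)
        return (S + S.T) / 2

    def test_lambda_zero_matches_inverse(self, rng):
        S = self._random_corr(rng, 6)
        T = e.glasso_solve(S, 0.0, tol=1e-7)
        assert np.abs(T - np.linalg.inv(S)).max() < 1e-6

    def test_full_sparsity_beyond_lambda_max(self, rng):
        S = self._random_corr(rng, 5)
        lam = np.abs(S - np.diag(np.diag(S))).max() * 1.01
        T = e.glasso_solve(S, lam)
        assert np.count_nonzero(np.triu(T, 1)) == 0

    def test_objective_matches_admm_oracle(self, rng):
        for _ in range(3):
            S = self._random_corr(rng, 4)
            lam = 0.1
            mine = e.glasso_solve(S, lam, tol=1e-6)
            oracle = admm_glasso(S, lam)
            assert glasso_objective(S, mine, lam) >= glasso_objective(S, oracle, lam) - 1e-5

    def test_objective_not_below_sklearn(self, rng):
        S = self._random_corr(rng, 7)
        lam = 0.12
        mine = e.glasso_solve(S, lam, tol=1e-6)
        _, sk = sk_glasso(S, alpha=lam, tol=1e-10, max_iter=2000)
        assert glasso_objective(S, mine, lam) >= glasso_objective(S, sk, lam) - 1e-5

    def test_kkt_certificate(self, rng):
        S = self._random_corr(rng, 8)
        lam = 0.05
        T = e.glasso_solve(S, lam, tol=1e-5)
        assert kkt_residual(S, T, lam) <= 1e-5

    def test_input_validation(self):
        with pytest.raises(ValueError):
            e.glasso_solve(np.ones((2, 3)), 0.1)
        with pytest.raises(ValueError):
            e.glasso_solve(np.eye(3), -0.5)


class TestEbic:
    def test_gamma_zero_reduces_to_bic(self, rng):
        S = np.corrcoef(rng.normal(size=(100, 3)).T)
        T = np.linalg.inv(S)
        n = 100
        val = e.ebic(T, S, n, gamma=0.0)
        sign, logdet = np.linalg.slogdet(T)
        L = 0.5 * n * (logdet - np.sum(S * T))
        E = np.count_nonzero(np.triu(T, 1))
        assert val == pytest.approx(-2 * L + E * np.log(n), rel=1e-12)

    def test_extra_edge_penalty_increment(self):
        n, p, gamma = 500, 4, 0.5
        S = np.eye(p)
        T1 = np.eye(p)
        T2 = T1.copy()
        T2[0, 1] = T2[1, 0] = 1e-9  # negligible likelihood change, one more edge
        diff = e.ebic(T2, S, n, gamma) - e.ebic(T1, S, n, gamma)
        assert diff == pytest.approx(np.log(n) + 4 * gamma * np.log(p), rel=1e-4)

    def test_hand_computed_three_variable_example(self):
        # worked example: T with one edge, all quantities written out
        S = np.array([[1.0, 0.5, 0.0], [0.5, 1.0, 0.0], [0.0, 0.0, 1.0]])
        T = np.array([[4 / 3, -2 / 3, 0.0], [-2 / 3, 4 / 3, 0.0], [0.0, 0.0, 1.0]])
        n, gamma = 100, 0.5
        logdet = np.log(4 / 3 * 4 / 3 - 4 / 9)  # det of 2x2 block, third is 1
        trace = 2 * (4 / 3) - 2 * 0.5 * (2 / 3) + 1.0
        L = 0.5 * n * (logdet - trace)
        expected = -2 * L + 1 * np.log(n) + 4 * gamma * 1 * np.log(3)
        assert e.ebic(T, S, n, gamma) == pytest.approx(expected, rel=1e-12)


class TestEbicGlasso:
    def test_selected_lambda_on_path(self, sz_std):
        fit = e.ebic_glasso(sz_std)
        assert np.any(np.isclose(fit.lambda_path, fit.lambda_selected))

    def test_partial_corr_shape_and_bounds(self, sz_std):
        fit = e.ebic_glasso(sz_std)
        pc = fit.partial_corr
        assert np.allclose(pc, pc.T)
        assert np.allclose(np.diag(pc), 0.0)
        assert np.abs(pc).max() <= 1.0

    def test_kkt_along_path(self, rng):
        X = rng.normal(size=(300, 6))
        X[:, 1] += 0.7 * X[:, 0]
        S = np.corrcoef(X.T)
        S = (S + S.T) / 2
        lams = _lambda_path(S, 25, 0.01)
        thetas, _ = _glasso_path_kernel(S, lams, 300, 0.5, 1e-7, 500, 1e-7)
        assert max(kkt_residual(S, thetas[i], lams[i]) for i in range(len(lams))) <= 1e-4

    def test_edge_count_grows_as_penalty_relaxes(self, rng):
        for _ in range(3):
            X = rng.normal(size=(250, 7)) @ (np.eye(7) + 0.25 * rng.normal(size=(7, 7)))
            S = np.corrcoef(X.T)
            S = (S + S.T) / 2
            lams = _lambda_path(S, 40, 0.01)
            thetas, _ = _glasso_path_kernel(S, lams, 250, 0.5, 1e-7, 500, 1e-7)
            counts = [int((np.abs(np.triu(thetas[i], 1)) > 1e-7).sum()) for i in range(len(lams))]
            # lams descend: support grows from empty to the path maximum,
            # never dipping more than one edge below the running maximum
            # (exact glasso supports are not strictly monotone)
            assert counts[0] == 0
            assert counts[-1] == max(counts)
            running = np.maximum.accumulate(counts)
            assert (running - np.asarray(counts)).max() <= 1

    def test_recovers_negative_mmn_p3a_edge(self, specs):
        """The strongest generated edge (negative ERP coupling) must appear
        with the right sign at the study's control sample size."""
        _, sz = specs
        hits = 0
        for rep in range(20):
            t = e.simulate(sz, 630, seed=1000 + rep)
            fit = e.ebic_glasso(e.standardize(t))
            if fit.edge_weight("MMN", "P3a") < 0:
                hits += 1
        assert hits == 20

    def test_independent_variables_give_empty_graph(self, rng):
        empties = 0
        for rep in range(20):
            X = np.random.default_rng(rep).normal(size=(600, 6))
            fit = e.ebic_glasso(e.standardize(X))
            empties += len(fit.edge_set) == 0
        assert empties >= 18


class TestBootstrapEdges:
    def test_deterministic_given_seed(self, rng):
        X = rng.normal(size=(120, 4))
        X[:, 1] += 0.8 * X[:, 0]
        std = e.standardize(X)
        a = e.bootstrap_edges(std, B=25, seed=5)
        b = e.bootstrap_edges(std, B=25, seed=5)
        assert np.array_equal(a.lower, b.lower) and np.array_equal(a.upper, b.upper)

    def test_strong_edge_interval_excludes_zero(self):
        hits = 0
        for rep in range(10):
            r = np.random.default_rng(rep)
            a = r.normal(size=600)
            b = 0.6 * a + 0.8 * r.normal(size=600)
            c = r.normal(size=600)
            boot = e.bootstrap_edges(e.standardize(np.column_stack([a, b, c])), B=100, seed=rep)
            if boot.lower[0, 1] > 0:
                hits += 1
        assert hits >= 9

    def test_interval_narrows_with_n(self):
        widths = []
        for n in (200, 2000):
            r = np.random.default_rng(0)
            a = r.normal(size=n)
            b = 0.5 * a + r.normal(size=n)
            boot = e.bootstrap_edges(e.standardize(np.column_stack([a, b])), B=100, seed=1)
            widths.append(boot.upper[0, 1] - boot.lower[0, 1])
        assert widths[1] < widths[0]


class TestPredictability:
    def test_isolated_node_zero(self, rng):
        X = np.random.default_rng(3).normal(size=(500, 4))
        fit = e.ebic_glasso(e.standardize(X))
        iso = [v for v in fit.variable_names if all(v not in p for p in fit.edge_set.sorted_pairs())]
        for v in iso:
            assert fit.predictability[v] == 0.0

    def test_deterministic_node_reaches_one(self, rng):
        a = rng.normal(size=400)
        b = rng.normal(size=400)
        c = 0.5 * a - 0.5 * b  # noise-free combination
        std = e.standardize(np.column_stack([a, b, c]))
        fit = e.ebic_glasso(std)
        assert fit.predictability[std.variable_names[2]] > 0.999

    def test_agrees_with_independent_ols(self, sz_std):
        import statsmodels.api as sm

        fit = e.ebic_glasso(sz_std)
        names = list(sz_std.variable_names)
        for j, v in enumerate(names):
            nb = [i for i, u in enumerate(names) if i != j and fit.partial_corr[i, j] != 0.0]
            if not nb:
                continue
            model = sm.OLS(sz_std.values[:, j], sm.add_constant(sz_std.values[:, nb])).fit()
            assert fit.predictability[v] == pytest.approx(model.rsquared, abs=1e-8)
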