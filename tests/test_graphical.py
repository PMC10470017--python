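"""Nodewise elastic-net estimation: eBIC, the penalized solver, network
assembly and min-abs symmetrization."""

import numpy as np
import pytest

from comornet import ising
from comornet._solver import enet_logistic_path, lambda_max
from comornet.containers import IsingNetwork, MorbidityMatrix, WeightMatrix
from comornet.graphical import (
    ElasticNetConfig,
    ebic,
    fit_network,
    fit_node,
    symmetrize_min_abs,
)

# 200 + 5*ln(1000) + 2*0.25*5*ln(99), evaluated independently
EBIC_EXAMPLE = 246.02657602024716


def matrix_from(values):
    values = np.asarray(values)
    return MorbidityMatrix(
        values=values,
        categories=[f"D{i:03d}" for i in range(values.shape[1])],
        row_ids=[f"S{i}" for i in range(values.shape[0])],
    )


class TestEbic:
    def test_no_coefficients_reduces_to_deviance(self):
        assert ebic(-123.4, 0, 500, 30, 0.25) == pytest.approx(246.8, abs=1e-12)

    def test_gamma_zero_is_bic(self):
        assert ebic(-50.0, 3, 200, 40, 0.0) == pytest.approx(100 + 3 * np.log(200), abs=1e-12)

    def test_reference_value(self):
        assert ebic(-100.0, 5, 1000, 99, 0.25) == pytest.approx(EBIC_EXAMPLE, abs=1e-10)

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            ebic(-1.0, 5, 1000, 3, 0.25)
        with pytest.raises(ValueError):
            ebic(-1.0, 0, 0, 3, 0.25)


@pytest.fixture(scope="module")
def xy():
    net = ising.random_network(8, 0.4, seed=31)
    data = ising.sample(net, 1200, n_sweeps=50, seed=32)
    X = data.values.astype(float)
    return np.ascontiguousarray(X[:, 1:]), X[:, 0].copy()


class TestSolver:
    def test_all_zero_at_and_above_lambda_max(self, xy):
        X, y = xy
        for alpha in (1.0, 0.9, 0.7):
            lmax = lambda_max(X, y, alpha)
            coefs, _, _ = enet_logistic_path(X, y, alpha, np.array([2 * lmax, lmax]))
            assert np.count_nonzero(coefs) == 0

    def test_matches_reference_solver(self, xy):
        """Cross-check against an unrelated solver (sklearn saga) at several
        points of the path, for pure LASSO and mixed penalties."""
        sklearn = pytest.importorskip("sklearn")
        from sklearn.linear_model import LogisticRegression

        X, y = xy
        n = len(y)
        for alpha in (1.0, 0.9):
            lmax = lambda_max(X, y, alpha)
            lams = np.geomspace(lmax, 0.01 * lmax, 20)
            coefs, b0s, _ = enet_logistic_path(X, y, alpha, lams)
            for li in (8, 19):
                clf = LogisticRegression(
                    solver="saga", l1_ratio=alpha, C=1.0 / (n * lams[li]),
                    max_iter=50000, tol=1e-10,
                )
                clf.fit(X, y)
                assert np.abs(coefs[li] - clf.coef_[0]).max() < 2e-3
                assert abs(b0s[li] - clf.intercept_[0]) < 2e-3

    def test_loglik_matches_direct_evaluation(self, xy):
        X, y = xy
        lmax = lambda_max(X, y, 0.9)
        lams = np.geomspace(lmax, 0.05 * lmax, 10)
        coefs, b0s, lls = enet_logistic_path(X, y, 0.9, lams)
        eta = b0s[-1] + X @ coefs[-1]
        direct = np.sum(y * eta - np.logaddexp(0.0, eta))
        assert lls[-1] == pytest.approx(direct, rel=1e-8)

    def test_rejects_bad_inputs(self, xy):
        X, y = xy
        with pytest.raises(ValueError, match="decreasing"):
            enet_logistic_path(X, y, 0.9, np.array([0.1, 0.2]))
        with pytest.raises(ValueError, match="binary"):
            enet_logistic_path(X + 0.1, y, 0.9, np.array([0.2, 0.1]))
        with pytest.raises(ValueError, match="constant"):
            enet_logistic_path(X, np.ones_like(y), 0.9, np.array([0.2, 0.1]))


class TestFitNode:
    def test_constant_outcome_error_names_category(self):
        vals = np.array([[1, 0], [1, 1], [1, 0], [1, 1]])
        with pytest.raises(ValueError, match="D000"):
            fit_node(matrix_from(vals), 0)

    def test_null_network_yields_empty_fits(self):
        """Data from a 3-node independence model: the eBIC-selected fit has
        no nonzero coefficients in nearly all replicates."""
        net = IsingNetwork(weights=np.zeros((3, 3)), thresholds=np.zeros(3))
        empty = 0
        n_rep = 100
        for rep in range(n_rep):
            data = ising.sample(net, 5000, n_sweeps=100, seed=1000 + rep)
            fit = fit_node(data, 0, ElasticNetConfig(alpha=0.9))
            empty += int(np.count_nonzero(fit.coefficients) == 0)
        assert empty >= 0.95 * n_rep

    def test_recovers_strong_conditional_dependence(self, chain3_network):
        data = ising.sample(chain3_network, 5000, n_sweeps=100, seed=55)
        fit = fit_node(data, 0, ElasticNetConfig(alpha=0.9))
        # outcome A: covariates are B, C in order
        assert fit.coefficients[0] > 0.5  # edge to B found
        assert fit.selected_lambda > 0
        assert np.isfinite(fit.ebic_value)


class TestFitNetwork:
    def test_shape_zero_diagonal_and_determinism(self, small_data):
        w1 = fit_network(small_data, ElasticNetConfig(alpha=0.9))
        w2 = fit_network(small_data, ElasticNetConfig(alpha=0.9))
        assert w1.values.shape == (small_data.p, small_data.p)
        assert np.all(np.diag(w1.values) == 0)
        assert not w1.symmetric
        assert np.array_equal(w1.values, w2.values)

    def test_independent_pair_gives_empty_network(self):
        net = IsingNetwork(weights=np.zeros((2, 2)), thresholds=np.zeros(2))
        data = ising.sample(net, 5000, n_sweeps=50, seed=13)
        w = fit_network(data, ElasticNetConfig(alpha=0.9))
        assert np.count_nonzero(w.values) == 0


class TestSymmetrizeMinAbs:
    def build(self, a01, a10):
        vals = np.array([[0.0, a01], [a10, 0.0]])
        return WeightMatrix(values=vals, categories=["A", "B"], symmetric=False)

    @pytest.mark.parametrize(
        "a01,a10,expected",
        [(2.0, 1.5, 1.5), (0.0, 3.0, 0.0), (-0.5, 0.8, -0.5)],
    )
    def test_min_abs_rule(self, a01, a10, expected):
        out = symmetrize_min_abs(self.build(a01, a10))
        assert out.symmetric
        assert out.values[0, 1] == expected
        assert out.values[1, 0] == expected

    def test_sign_conflict_tie_keeps_row_major(self):
        out = symmetrize_min_abs(self.build(0.7, -0.7))
        assert out.values[0, 1] == 0.7

    def test_idempotent_values(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=(5, 5))
        np.fill_diagonal(a, 0)
        w = WeightMatrix(values=a, categories=list("ABCDE"), symmetric=False)
        once = symmetrize_min_abs(w)
        again = symmetrize_min_abs(
            WeightMatrix(values=once.values.copy(), categories=list("ABCDE"), symmetric=False)
        )
        assert np.array_equal(once.values, again.values)

    def test_commutes_with_relabeling(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=(6, 6))
        np.fill_diagonal(a, 0)
        perm = rng.permutation(6)
        cats = [f"D{i}" for i in range(6)]
        direct = symmetrize_min_abs(WeightMatrix(a, cats, symmetric=False)).values
        permuted = symmetrize_min_abs(
            WeightMatrix(a[np.ix_(perm, perm)], [cats[i] for i in perm], symmetric=False)
        ).values
        assert np.allclose(direct[np.ix_(perm, perm)], permuted)

    def test_rejects_already_symmetric(self):
        w = WeightMatrix(np.zeros((2, 2)), ["A", "B"], symmetric=True)
        with pytest.raises(ValueError):
            symmetrize_min_abs(w)
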