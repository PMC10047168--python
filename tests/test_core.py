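"""Laplacian, null eigenvector, Jacobian and critical-point machinery."""

import numpy as np
import pytest

import rwagraph as rw
from rwagraph.core import null_eigenvector_many
from rwagraph.exceptions import (
    BoundaryDerivativeError,
    DisconnectedGraphError,
    InvalidModelError,
)

from conftest import random_simplex_points


def brute_force_toy_laplacian(alpha, x):
    """Element-wise assembly of L = diag(d) - pi from the four toy rate formulas."""
    theta = lambda z: 1 - alpha + alpha * (1 - z) ** 2
    pi = np.zeros((3, 3))
    pi[0, 1] = 1.0
    pi[1, 0] = theta(x[0])
    pi[2, 1] = 1.0
    pi[1, 2] = theta(x[2])
    d = [pi[:, k].sum() for k in range(3)]
    L = np.zeros((3, 3))
    for k in range(3):
        for i in range(3):
            L[k, i] = (d[k] if k == i else 0.0) - pi[k, i]
    return L


class TestLaplacian:
    def test_two_state_constant(self, linear_2state):
        L = rw.laplacian(linear_2state, np.array([0.5, 0.5]))
        np.testing.assert_allclose(L, [[1.0, -1.0], [-1.0, 1.0]])

    def test_toy_alpha0_rates_are_unity(self):
        pi = rw.core.rate_matrix(rw.toy_model(0.0), np.array([0.2, 0.5, 0.3]))
        assert {pi[0, 1], pi[1, 0], pi[2, 1], pi[1, 2]} == {1.0}

    def test_matches_brute_force_assembly(self):
        x = np.array([0.3, 0.4, 0.3])
        L = rw.laplacian(rw.toy_model(0.5), x)
        np.testing.assert_allclose(L, brute_force_toy_laplacian(0.5, x), atol=1e-14)

    @pytest.mark.parametrize("model_name", ["toy", "pdpc"])
    def test_column_sums_vanish(self, model_name):
        model = rw.make_model(model_name)
        for x in random_simplex_points(20, seed=3):
            assert np.abs(rw.laplacian(model, x).sum(axis=0)).max() == pytest.approx(0.0, abs=1e-14)

    def test_negative_rate_rejected(self):
        bad = rw.StateGraphModel(M=2, rates=lambda x: np.array([[0.0, -1.0], [1.0, 0.0]]))
        with pytest.raises(InvalidModelError):
            rw.laplacian(bad, np.array([0.5, 0.5]))


class TestNullEigenvector:
    def test_toy_linear_is_uniform(self):
        p = rw.null_eigenvector(rw.toy_model(0.0), np.array([0.1, 0.2, 0.7]))
        np.testing.assert_allclose(p, np.full(3, 1 / 3), atol=1e-12)

    def test_two_state_detailed_balance(self, linear_2state_asym):
        p = rw.null_eigenvector(linear_2state_asym, np.array([0.5, 0.5]))
        np.testing.assert_allclose(p, [2 / 3, 1 / 3], atol=1e-12)

    @pytest.mark.parametrize("model_name,params", [("toy", {"alpha": 0.7}), ("pdpc", {"v2": 2.8})])
    def test_closed_form_matches_generic_eigensolve(self, model_name, params):
        """The 3-state chain closed form agrees with a dense eigensolve of L."""
        model = rw.make_model(model_name, **params)
        for x in random_simplex_points(25, seed=11):
            p_closed = rw.null_eigenvector(model, x)
            L = rw.laplacian(model, x)
            vals, vecs = np.linalg.eig(L)
            v = vecs[:, np.argmin(np.abs(vals))].real
            v = v / v.sum()
            np.testing.assert_allclose(p_closed, v, atol=1e-10)
            assert np.abs(L @ p_closed).max() < 1e-10

    def test_residual_small_on_random_points(self):
        model = rw.pdpc_model()
        for x in random_simplex_points(100, seed=5):
            p = rw.null_eigenvector(model, x)
            assert np.abs(rw.laplacian(model, x) @ p).max() < 1e-10
            assert p.min() >= 0 and p.sum() == pytest.approx(1.0, abs=1e-12)

    def test_disconnected_graph_raises(self):
        # two isolated 2-cycles within a 4-state graph: degenerate null space
        def rates(x):
            pi = np.zeros((4, 4))
            pi[0, 1] = pi[1, 0] = 1.0
            pi[2, 3] = pi[3, 2] = 1.0
            return pi

        model = rw.StateGraphModel(M=4, rates=rates)
        with pytest.raises(DisconnectedGraphError):
            rw.null_eigenvector(model, np.full(4, 0.25))

    def test_vectorized_matches_scalar(self, toy04):
        X = random_simplex_points(30, seed=7).T
        P = null_eigenvector_many(toy04, X)
        for k in range(X.shape[1]):
            np.testing.assert_allclose(P[:, k], rw.null_eigenvector(toy04, X[:, k]), atol=1e-13)


class TestDeterministicRhs:
    def test_zero_at_critical_point(self, toy04):
        cp = rw.find_critical_points(toy04)[0]
        assert np.abs(rw.deterministic_rhs(toy04, cp.x_star)).max() < 1e-9

    def test_flow_conserves_total_density(self):
        model = rw.toy_model(0.0)
        f = rw.deterministic_rhs(model, np.array([1.0, 0.0, 0.0]))
        assert f.sum() == pytest.approx(0.0, abs=1e-14)
        assert f[0] < 0  # flow away from the crowded corner

    def test_pdpc_symmetric_point_is_stationary(self):
        """The symmetric critical state exists for every v2."""
        for v2 in (1.5, 2.5, 3.5):
            params = rw.PdpcParams(v2=v2)
            x1 = rw.pdpc_critical_points(params)[0]
            assert np.abs(rw.deterministic_rhs(rw.pdpc_model(params), x1)).max() < 1e-10


class TestJacobian:
    def test_linear_model_has_zero_jacobian(self, linear_3state):
        J = rw.jacobian_p(linear_3state, np.array([0.3, 0.3, 0.4]))
        np.testing.assert_allclose(J, 0.0, atol=1e-9)

    def test_rows_sum_to_zero(self, toy04):
        """Normalization of p forces sum_k dp_k/dx_i = 0."""
        for x in random_simplex_points(20, seed=13):
            J = rw.jacobian_p(toy04, x)
            np.testing.assert_allclose(J.sum(axis=1), 0.0, atol=1e-6)

    def test_richardson_step_halving(self):
        """Central differences are consistent under step halving at the symmetric point."""
        model = rw.toy_model(0.5)
        x = rw.find_critical_points(model)[0].x_star
        J1 = rw.jacobian_p(model, x, h=1e-5)
        J2 = rw.jacobian_p(model, x, h=5e-6)
        np.testing.assert_allclose(J1, J2, atol=1e-7)

    def test_boundary_step_raises(self, toy04):
        with pytest.raises(BoundaryDerivativeError):
            rw.jacobian_p(toy04, np.array([1.0, 0.0, 0.0]), h=1e-6)


class TestCriticalPoints:
    def test_toy_linear_unique_symmetric(self):
        cps = rw.find_critical_points(rw.toy_model(0.0))
        assert len(cps) == 1
        np.testing.assert_allclose(cps[0].x_star, np.full(3, 1 / 3), atol=1e-10)
        assert cps[0].stable

    def test_pdpc_bistable_three_points(self, pdpc_bi):
        cps = rw.find_critical_points(pdpc_bi)
        assert len(cps) == 3
        analytic = rw.pdpc_critical_points(rw.PdpcParams(v2=3.04))
        for target in analytic:
            assert min(np.max(np.abs(c.x_star - target)) for c in cps) < 1e-8
        symmetric = [c for c in cps if abs(c.x_star[0] - c.x_star[2]) < 1e-8]
        assert len(symmetric) == 1 and not symmetric[0].stable
        assert sum(c.stable for c in cps) == 2

    def test_pdpc_monostable_single_point(self, pdpc_mono):
        cps = rw.find_critical_points(pdpc_mono)
        assert len(cps) == 1 and cps[0].stable
        np.testing.assert_allclose(
            cps[0].x_star, rw.pdpc_critical_points(rw.PdpcParams(v2=1.82))[0], atol=1e-9
        )

    def test_self_consistency_residual(self, pdpc_bi):
        for c in rw.find_critical_points(pdpc_bi):
            assert np.abs(rw.null_eigenvector(pdpc_bi, c.x_star) - c.x_star).sum() < 1e-9


class TestBifurcationScan:
    def test_linear_family_never_crosses(self):
        with pytest.warns(UserWarning):
            scan = rw.bifurcation_scan(lambda a: rw.toy_model(0.0), [0.0, 0.5, 1.0])
        assert scan.crossing is None
        np.testing.assert_allclose(scan.table["indicator"], 0.0, atol=1e-8)

    def test_pdpc_crossing_at_known_threshold(self):
        scan = rw.bifurcation_scan(
            lambda v2: rw.pdpc_model(rw.PdpcParams(v2=v2)), np.linspace(1.5, 3.5, 9)
        )
        assert scan.crossing == pytest.approx(2.5, abs=1e-3)
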