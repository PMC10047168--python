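"""Exact master-equation machinery: generator, null-space, RK, Gillespie, relaxation."""

import numpy as np
import pytest
from scipy.stats import multinomial

import rwagraph as rw
from rwagraph.exceptions import InsufficientDataError

from conftest import make_linear3


def eq17_rhs_toy(alpha, N, lattice, rho):
    """Independent term-by-term assembly of the three-state one-step balance.

    Gain and loss terms written directly per hop direction, with rates
    evaluated at the source state's density (rescaled time: propensity
    pi_ij(x) * n_j)."""
    theta = lambda z: 1 - alpha + alpha * (1 - z) ** 2
    out = np.zeros_like(rho)
    for idx, (nA, nB, nC) in enumerate(lattice.states.tolist()):
        x = np.array([nA, nB, nC]) / N

        def p_of(state):
            try:
                return rho[lattice.index_of(state)]
            except KeyError:
                return 0.0

        # B->A gain from (nA-1, nB+1, nC) and loss
        if nA >= 1:
            out[idx] += 1.0 * (nB + 1) * p_of((nA - 1, nB + 1, nC))
        out[idx] -= 1.0 * nB * rho[idx]
        # A->B gain from (nA+1, nB-1, nC) and loss
        if nB >= 1:
            out[idx] += theta((nA + 1) / N) * (nA + 1) * p_of((nA + 1, nB - 1, nC))
        out[idx] -= theta(nA / N) * nA * rho[idx]
        # B->C gain from (nA, nB+1, nC-1) and loss
        if nC >= 1:
            out[idx] += 1.0 * (nB + 1) * p_of((nA, nB + 1, nC - 1))
        out[idx] -= 1.0 * nB * rho[idx]
        # C->B gain from (nA, nB-1, nC+1) and loss
        if nB >= 1:
            out[idx] += theta((nC + 1) / N) * (nC + 1) * p_of((nA, nB - 1, nC + 1))
        out[idx] -= theta(nC / N) * nC * rho[idx]
    return out


class TestGenerator:
    @pytest.mark.parametrize("model_name,params,N", [("toy", {"alpha": 0.7}, 8), ("pdpc", {"v2": 3.04}, 6)])
    def test_columns_conserve_probability(self, model_name, params, N):
        gen = rw.build_generator(rw.make_model(model_name, **params), N)
        cols = np.asarray(gen.W.sum(axis=0)).ravel()
        assert np.abs(cols).max() < 1e-12

    def test_one_step_structure(self, toy04):
        gen = rw.build_generator(toy04, 5)
        W = gen.W.tocoo()
        for r, c in zip(W.row, W.col):
            if r == c:
                continue
            diff = gen.lattice.states[r] - gen.lattice.states[c]
            assert sorted(diff.tolist()) == [-1, 0, 1]

    def test_two_state_binomial_null_vector(self, linear_2state):
        """Hand-solved 3-state chain: stationary of N=2 symmetric walk is Binomial(2, 1/2)."""
        gen = rw.build_generator(linear_2state, 2)
        dist = rw.stationary_nullspace(gen)
        np.testing.assert_allclose(dist.prob, [0.25, 0.5, 0.25], atol=1e-12)

    def test_matches_term_by_term_assembly(self):
        """Generator action equals an independent explicit assembly of all eight terms."""
        alpha, N = 0.5, 3
        model = rw.toy_model(alpha)
        gen = rw.build_generator(model, N)
        rng = np.random.default_rng(0)
        rho = rng.dirichlet(np.ones(gen.lattice.size))
        np.testing.assert_allclose(
            gen.W @ rho, eq17_rhs_toy(alpha, N, gen.lattice, rho), atol=1e-13
        )


class TestStationaryNullspace:
    def test_linear_model_multinomial(self, linear_3state):
        N = 30
        dist = rw.stationary_nullspace(rw.build_generator(linear_3state, N))
        p = rw.null_eigenvector(linear_3state, np.full(3, 1 / 3))
        expected = multinomial.pmf(dist.lattice.states, n=N, p=p)
        np.testing.assert_allclose(dist.prob, expected, atol=1e-9)

    def test_random_constant_rate_models_multinomial(self):
        rng = np.random.default_rng(42)
        for _ in range(3):
            p_target = rng.dirichlet(np.ones(3))
            model = make_linear3(tuple(p_target))
            N = 15
            dist = rw.stationary_nullspace(rw.build_generator(model, N))
            p = rw.null_eigenvector(model, np.full(3, 1 / 3))
            expected = multinomial.pmf(dist.lattice.states, n=N, p=p)
            np.testing.assert_allclose(dist.prob, expected, atol=1e-9)

    def test_residual_below_threshold(self, toy04):
        gen = rw.build_generator(toy04, 60)
        dist = rw.stationary_nullspace(gen)
        assert np.abs(gen.W @ dist.prob).sum() < 1e-10


class TestIntegration:
    def test_stationary_start_returns_immediately(self, toy04, exact_solution):
        gen = rw.build_generator(toy04, 40)
        stat = rw.stationary_nullspace(gen)
        dist, trace = rw.integrate_to_stationarity(gen, stat)
        assert trace.shape[0] == 1  # converged at step 0
        assert rw.l1_distance(dist, stat) == 0.0

    def test_agrees_with_nullspace(self, toy04, exact_solution):
        N = 100
        gen = rw.build_generator(toy04, N)
        ns = exact_solution(toy04, N)
        uniform = rw.LatticeDistribution.from_weights(gen.lattice, np.ones(gen.lattice.size))
        rk, trace = rw.integrate_to_stationarity(gen, uniform)
        assert rw.l1_distance(rk, ns) < 1e-7
        # conservation along the trajectory is maintained by construction;
        # the recorded distances decrease toward 0
        assert trace[-1, 1] == 0.0
        assert np.all(np.diff(trace[:5, 1]) <= 0)


class TestGillespie:
    def test_two_state_converges_to_exact(self, linear_2state):
        dist = rw.gillespie_sample(linear_2state, 2, n_events=200_000, burn_in=1_000, seed=3)
        assert np.abs(dist.prob - np.array([0.25, 0.5, 0.25])).sum() < 0.03

    def test_deterministic_given_seed(self, toy04):
        a = rw.gillespie_sample(toy04, 10, n_events=5_000, burn_in=100, seed=7)
        b = rw.gillespie_sample(toy04, 10, n_events=5_000, burn_in=100, seed=7)
        assert np.array_equal(a.prob, b.prob)

    def test_different_seed_differs(self, toy04):
        a = rw.gillespie_sample(toy04, 10, n_events=5_000, burn_in=100, seed=7)
        b = rw.gillespie_sample(toy04, 10, n_events=5_000, burn_in=100, seed=8)
        assert not np.array_equal(a.prob, b.prob)

    def test_invalid_event_counts(self, toy04):
        with pytest.raises(ValueError):
            rw.gillespie_sample(toy04, 10, n_events=100, burn_in=100)


class TestRelaxationRate:
    def test_pure_exponential(self):
        t = np.linspace(0, 5, 60)
        trace = np.column_stack([t, np.exp(-3 * t)])
        assert rw.relaxation_rate(trace) == pytest.approx(3.0, rel=1e-6)

    def test_linear_model_rate_is_spectral_gap(self, linear_2state):
        """Fitted relaxation equals the generator's smallest nonzero eigenvalue."""
        N = 6
        gen = rw.build_generator(linear_2state, N)
        vals = np.linalg.eigvals(gen.W.toarray())
        gap = sorted(np.abs(vals.real))[1]
        stat = rw.stationary_nullspace(gen)
        rho0 = np.zeros(gen.lattice.size)
        rho0[gen.lattice.index_of((N, 0))] = 1.0
        trace = rw.relaxation_trace(
            gen, rw.LatticeDistribution.from_weights(gen.lattice, rho0), stat, t_max=8.0
        )
        assert rw.relaxation_rate(trace) == pytest.approx(gap, rel=0.05)

    def test_too_short_series_raises(self):
        with pytest.raises(InsufficientDataError):
            rw.relaxation_rate(np.array([[0.0, 1.0], [1.0, 0.5]]))
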