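import numpy as np
import pytest
from hypothesis import settings

import rwagraph as rw

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=30)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def linear_2state():
    """Constant-rate 2-state model pi_12 = pi_21 = 1."""

    def rates(x):
        return np.array([[0.0, 1.0], [1.0, 0.0]])

    return rw.StateGraphModel(M=2, rates=rates, name="linear2")


@pytest.fixture(scope="session")
def linear_2state_asym():
    """Constant-rate 2-state model pi_12 = 2, pi_21 = 1."""

    def rates(x):
        return np.array([[0.0, 2.0], [1.0, 0.0]])

    return rw.StateGraphModel(M=2, rates=rates, name="linear2a")


def make_linear3(p_target, scale=1.0):
    """A constant-rate 3-state chain whose null eigenvector is ``p_target``."""
    pA, pB, pC = p_target

    def rates(x):
        pi = np.zeros((3, 3))
        pi[0, 1] = scale * pA / pB  # B -> A
        pi[1, 0] = scale * 1.0  # A -> B
        pi[2, 1] = scale * pC / pB  # B -> C
        pi[1, 2] = scale * 1.0  # C -> B
        return pi

    def rates_many(X):
        K = X.shape[1]
        pi = np.zeros((3, 3, K))
        pi[0, 1] = scale * pA / pB
        pi[1, 0] = scale
        pi[2, 1] = scale * pC / pB
        pi[1, 2] = scale
        return pi

    return rw.StateGraphModel(
        M=3, rates=rates, name="linear3", params={"p": tuple(p_target)}, rates_many=rates_many
    )


@pytest.fixture(scope="session")
def linear_3state():
    return make_linear3((0.2, 0.3, 0.5))


@pytest.fixture(scope="session")
def toy04():
    return rw.toy_model(0.4)


@pytest.fixture(scope="session")
def pdpc_mono():
    return rw.pdpc_model(rw.PdpcParams(v2=1.82))


@pytest.fixture(scope="session")
def pdpc_bi():
    return rw.pdpc_model(rw.PdpcParams(v2=3.04))


_EXACT_CACHE = {}


@pytest.fixture(scope="session")
def exact_solution():
    """Session-cached exact stationary distributions keyed by (model name, params, N)."""

    def solve(model, N, lattice=None):
        key = (model.name, tuple(sorted(model.params.items())), N)
        if key not in _EXACT_CACHE:
            gen = rw.build_generator(model, N, lattice=lattice)
            _EXACT_CACHE[key] = rw.stationary_nullspace(gen)
        return _EXACT_CACHE[key]

    return solve


def random_simplex_points(n, M=3, seed=0):
    rng = np.random.default_rng(seed)
    return rng.dirichlet(np.ones(M), size=n)
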