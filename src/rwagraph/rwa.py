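"""The Random Walk Approximation (RWA) of the stationary master-equation solution.

For a linear random walk of N independent particles on a graph, the
stationary distribution over occupation vectors n is the multinomial built
from the Laplacian null eigenvector p.  The RWA keeps the multinomial shape
but lets p depend on the state's own density x = n/N:

    rho(n) = C(N) * N! * prod_k p_k(n/N)^{n_k} / n_k!

C(N) is fixed by normalization over the conserved-N lattice (computed here by
exact summation, which for the lattice sizes of interest is cheap and removes
one approximation layer).  For constant rates the RWA is the exact multinomial
stationary solution; in general its l1 deviation from the true stationary
distribution is of the order of the norm of dp/dx at the stable critical
point, independently of N.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, logsumexp

from .core import (
    StateGraphModel,
    find_critical_points,
    jacobian_p,
    null_eigenvector_many,
)
from .exceptions import NoCriticalPointError
from .lattice import LatticeDistribution, SimplexLattice, enumerate_lattice, local_modes

__all__ = [
    "RwaResult",
    "Mode",
    "rwa_distribution",
    "rwa_log_weights",
    "me_residual_l1",
    "jacobian_norm_bound",
    "mode_check",
]


@dataclass
class RwaResult:
    """RWA distribution together with its normalization and error diagnostics.

    ``log_norm`` is log C(N); ``jacobian_norm`` is the spectral norm of
    dp/dx at the stable critical point (NaN when the model has none), the
    predicted scale of the l1 error.
    """

    dist: LatticeDistribution
    log_norm: float
    jacobian_norm: float


@dataclass(frozen=True)
class Mode:
    """A local maximum of a lattice distribution.

    ``consistent`` marks modes whose density lies within 2/N (inf-norm) of a
    self-consistent critical point; others are spurious RWA artifacts that can
    appear at or beyond a bifurcation.
    """

    state: tuple
    density: np.ndarray
    prob: float
    consistent: bool


def rwa_log_weights(model: StateGraphModel, lattice: SimplexLattice) -> np.ndarray:
    """Unnormalized log-weights log(N! prod p_k(n/N)^{n_k}/n_k!) per lattice state.

    Evaluated entirely in log space (N! overflows double precision at
    N ~ 171).  The convention 0 * log 0 = 0 applies: states with n_k = 0
    ignore p_k, and p_k = 0 with n_k > 0 yields log-weight -inf (probability
    zero), not an error.
    """
    N = lattice.N
    P = null_eigenvector_many(model, lattice.states.T / N)  # (M, size)
    n = lattice.states.T  # (M, size)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(n > 0, n * np.log(P), 0.0)
    terms = np.where((n > 0) & (P == 0.0), -np.inf, terms)
    return gammaln(N + 1) - gammaln(n + 1.0).sum(axis=0) + terms.sum(axis=0)


def rwa_distribution(
    model: StateGraphModel, N: int, lattice: SimplexLattice | None = None
) -> RwaResult:
    """Build the RWA stationary distribution on the |n| = N lattice.

    The null eigenvector p is evaluated at each state's own density n/N
    (boundary states included: boundary densities are valid simplex points).
    Normalization over the lattice defines C(N).
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    if lattice is None:
        lattice = enumerate_lattice(N, model.M)
    logw = rwa_log_weights(model, lattice)
    lse = logsumexp(logw)
    prob = np.exp(logw - lse)
    dist = LatticeDistribution.from_weights(lattice, prob)
    try:
        jnorm = jacobian_norm_bound(model)
    except NoCriticalPointError:
        jnorm = float("nan")
    return RwaResult(dist=dist, log_norm=float(-lse), jacobian_norm=jnorm)


def me_residual_l1(model: StateGraphModel, dist: LatticeDistribution) -> float:
    """l1 norm of the master-equation generator applied to a distribution.

    Zero exactly when ``dist`` is stationary; for the RWA this residual is the
    paper-level l1-error estimate and is O(||dp/dx||), independent of N.
    """
    from .exact import build_generator

    gen = build_generator(model, dist.lattice.N, lattice=dist.lattice)
    return float(np.abs(gen.W @ dist.prob).sum())


def jacobian_norm_bound(model: StateGraphModel, seed: int = 0) -> float:
    """Spectral norm of dp/dx at the stable critical point.

    This is the predicted scale of the l1 error of the RWA; it is 0 for
    linear models (constant p) and grows toward the bifurcation.
    """
    cps = find_critical_points(model, seed=seed)
    stable = [c for c in cps if c.stable]
    if not stable:
        raise NoCriticalPointError(f"model {model.name!r} has no stable critical point")
    # for multistable models all stable points are equivalent by symmetry;
    # report the largest norm to be conservative
    return max(float(np.linalg.norm(jacobian_p(model, c.x_star), 2)) for c in stable)


def mode_check(
    model: StateGraphModel, result: RwaResult, seed: int = 0, tol_states: float = 2.0
) -> list[Mode]:
    """Locate the lattice modes of an RWA distribution and flag spurious ones.

    Local maxima are taken over the one-step neighbor moves n -> n + e_i - e_j
    (the adjacency of the process itself).  A mode is ``consistent`` when its
    density lies within ``tol_states``/N (inf-norm) of a self-consistent
    critical point p(x*) = x*; at or beyond a bifurcation the RWA may acquire
    spurious stationary points, which this check reports but does not repair.
    """
    dist = result.dist
    N = dist.lattice.N
    cps = find_critical_points(model, seed=seed)
    modes = []
    for idx in local_modes(dist):
        n = dist.lattice.states[idx]
        x = n / N
        consistent = any(
            np.max(np.abs(x - c.x_star)) <= tol_states / N + 1e-12 for c in cps
        )
        modes.append(
            Mode(state=tuple(int(v) for v in n), density=x, prob=float(dist.prob[idx]), consistent=consistent)
        )
    return modes
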