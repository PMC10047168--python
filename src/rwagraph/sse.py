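"""System Size Expansion (linear-noise) and linearized-multinomial benchmarks.

The SSE approximates the stationary distribution around each stable critical
point x* by a Gaussian in the density fluctuation dx = x - x*, with
covariance Sigma solving the continuous Lyapunov equation

    Abar Sigma + Sigma Abar^T = D*,

where -Abar is the Jacobian of the deterministic flow dx/dt = -L(x) x at x*
and D* is the one-step diffusion matrix (carrying the 1/N system-size
factor).  The conservation constraint makes the full M x M problem singular,
so everything is reduced to independent coordinates ((x_A, x_C) for the
three-state models); in these coordinates D is diagonal for chain-topology
models because A<->B moves change only n_A and C<->B moves only n_C.

The linearized multinomial freezes p at p(x*) and uses the linear-case
multinomial stationary solution directly.  In a bistable regime both methods
place one component per stable critical point with equal weights (justified
by the exact A<->C symmetry of the shipped models).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
from scipy.special import gammaln, logsumexp

from .core import (
    CriticalPoint,
    StateGraphModel,
    deterministic_rhs,
    find_critical_points,
    laplacian,
    null_eigenvector,
)
from .exceptions import (
    NoCriticalPointError,
    SingularLyapunovError,
    UnstableExpansionPointError,
)
from .lattice import LatticeDistribution, SimplexLattice, enumerate_lattice

__all__ = [
    "GaussianComponent",
    "drift_and_diffusion",
    "solve_lyapunov",
    "sse_components",
    "sse_distribution",
    "multinomial_approximation",
]


@dataclass
class GaussianComponent:
    """One Gaussian of the SSE mixture: mean x*, reduced covariance, weight."""

    mean: np.ndarray
    sigma: np.ndarray
    weight: float


def _kept_indices(M: int) -> list[int]:
    # independent coordinates after eliminating the conservation constraint:
    # (A, C) for three-state models, all but the last state otherwise
    return [0, 2] if M == 3 else list(range(M - 1))


def _diffusion(model: StateGraphModel, x: np.ndarray, N: int) -> np.ndarray:
    """One-step diffusion matrix D(x) (full M x M), including the 1/N factor."""
    pi = laplacian(model, x)  # validates rates
    pi = np.diag(np.diag(pi)) - pi  # recover the rate matrix from L
    flux = pi * x[None, :]  # flux[i, j] = pi_ij x_j
    D = -(flux + flux.T)
    np.fill_diagonal(D, 0.0)
    d = (flux + flux.T).sum(axis=1) - 2 * np.diag(flux)
    D[np.diag_indices_from(D)] = d
    return D / N


def drift_and_diffusion(
    model: StateGraphModel, x_star: CriticalPoint | np.ndarray, N: int, h: float = 1e-6
) -> tuple[np.ndarray, np.ndarray]:
    """Reduced drift matrix Abar and diffusion matrix D* at a stable critical point.

    Abar is built from the Laplacian and its finite-difference derivatives,
    Abar_ij = L*_ij + sum_k (dL_ik/dx_j) x*_k, reduced to the independent
    coordinates by the chain rule for the eliminated (dependent) density.  The
    sign convention is validated programmatically: -Abar must equal the
    numerical Jacobian of the reduced deterministic flow, and an AssertionError
    is raised otherwise.  D* is the one-step diffusion matrix at x*, reduced
    likewise; it carries the 1/N factor.

    Raises
    ------
    UnstableExpansionPointError
        If ``x_star`` is a :class:`CriticalPoint` flagged unstable.
    """
    if isinstance(x_star, CriticalPoint):
        if not x_star.stable:
            raise UnstableExpansionPointError("SSE requested at an unstable critical point")
        x = x_star.x_star
    else:
        x = np.asarray(x_star, dtype=float)
    M = model.M
    kept = _kept_indices(M)
    ref = [i for i in range(M) if i not in kept][0]

    # full-coordinate Abar via plain partial derivatives of L (the model rate
    # formulas extend smoothly off the simplex)
    L0 = laplacian(model, x)
    A_full = L0.copy()
    for j in range(M):
        d = np.zeros(M)
        d[j] = h
        dL = (laplacian(model, x + d) - laplacian(model, x - d)) / (2 * h)
        A_full[:, j] += dL @ x
    # chain rule: x_ref = 1 - sum of kept coordinates
    A_red = A_full[np.ix_(kept, kept)] - A_full[np.ix_(kept, [ref])]

    # loud sign-convention check against the reduced flow Jacobian
    def flow_red(z):
        xx = np.empty(M)
        xx[kept] = z
        xx[ref] = 1.0 - z.sum()
        return deterministic_rhs(model, xx)[kept]

    z0 = x[kept]
    J_num = np.empty((len(kept), len(kept)))
    for j in range(len(kept)):
        dz = np.zeros(len(kept))
        dz[j] = h
        J_num[:, j] = (flow_red(z0 + dz) - flow_red(z0 - dz)) / (2 * h)
    if not np.allclose(-A_red, J_num, rtol=1e-4, atol=1e-6):
        raise AssertionError(
            "sign-convention check failed: -Abar does not match the numerical "
            "Jacobian of the reduced deterministic flow"
        )

    D_red = _diffusion(model, x, N)[np.ix_(kept, kept)]
    return A_red, D_red


def solve_lyapunov(A: np.ndarray, D: np.ndarray, residual_tol: float = 1e-10) -> np.ndarray:
    """Solve Abar Sigma + Sigma Abar^T = D for the stationary covariance Sigma.

    Abar must be stable in the convention used here (eigenvalues with
    positive real part, i.e. -Abar is the flow Jacobian).

    Raises
    ------
    SingularLyapunovError
        If Abar has an eigenvalue at (or numerically near) 0, as happens at a
        bifurcation.
    """
    A = np.asarray(A, dtype=float)
    D = np.asarray(D, dtype=float)
    eigs = np.linalg.eigvals(A)
    if np.min(eigs.real) < 1e-12 * max(1.0, np.abs(eigs).max()):
        raise SingularLyapunovError(
            f"drift matrix has eigenvalue with real part {np.min(eigs.real):.2e}; "
            "the Lyapunov equation is singular at a bifurcation"
        )
    if np.allclose(D, 0.0):
        return np.zeros_like(D)
    # scipy solves a x + x a^H + q = 0; ours is A Sigma + Sigma A^T = D
    sigma = scipy.linalg.solve_continuous_lyapunov(A, D)
    sigma = 0.5 * (sigma + sigma.T)
    res = np.linalg.norm(A @ sigma + sigma @ A.T - D, "fro")
    if res > max(residual_tol, 1e-12 * np.linalg.norm(sigma, "fro")):
        raise SingularLyapunovError(f"Lyapunov residual {res:.2e} too large")
    return sigma


def sse_components(model: StateGraphModel, N: int, seed: int = 0) -> list[GaussianComponent]:
    """One equally-weighted Gaussian component per stable critical point."""
    cps = [c for c in find_critical_points(model, seed=seed) if c.stable]
    if not cps:
        raise NoCriticalPointError("SSE needs at least one stable critical point")
    comps = []
    for c in cps:
        A, D = drift_and_diffusion(model, c, N)
        sigma = solve_lyapunov(A, D)
        comps.append(GaussianComponent(mean=c.x_star, sigma=sigma, weight=1.0 / len(cps)))
    return comps


def sse_distribution(
    model: StateGraphModel,
    N: int,
    lattice: SimplexLattice | None = None,
    seed: int = 0,
    return_components: bool = False,
):
    """SSE Gaussian (mixture) discretized and renormalized on the |n| = N lattice.

    The Gaussian kernel exp(-dz^T Sigma^-1 dz / 2) is evaluated at every
    lattice state's reduced density and the mixture renormalized over the
    lattice, which makes the continuous normalizing prefactor irrelevant.
    """
    if lattice is None:
        lattice = enumerate_lattice(N, model.M)
    comps = sse_components(model, N, seed=seed)
    kept = _kept_indices(model.M)
    Z = lattice.states[:, kept] / N  # (size, r)
    logs = np.full((len(comps), lattice.size), -np.inf)
    for k, comp in enumerate(comps):
        dz = Z - comp.mean[kept]
        sol = np.linalg.solve(comp.sigma, dz.T)
        logs[k] = np.log(comp.weight) - 0.5 * np.einsum("ij,ji->i", dz, sol)
    logw = logsumexp(logs, axis=0)
    prob = np.exp(logw - logsumexp(logw))
    dist = LatticeDistribution.from_weights(lattice, prob)
    if return_components:
        return dist, comps
    return dist


def multinomial_approximation(
    model: StateGraphModel,
    N: int,
    lattice: SimplexLattice | None = None,
    seed: int = 0,
) -> LatticeDistribution:
    """Linearized multinomial: the linear-case solution with p frozen at p(x*).

    One multinomial component per stable critical point (equal weights),
    normalized over the lattice.  Exact for genuinely linear models.
    """
    if lattice is None:
        lattice = enumerate_lattice(N, model.M)
    cps = [c for c in find_critical_points(model, seed=seed) if c.stable]
    if not cps:
        raise NoCriticalPointError("multinomial approximation needs a stable critical point")
    n = lattice.states.T  # (M, size)
    log_base = gammaln(N + 1) - gammaln(n + 1.0).sum(axis=0)
    logs = np.full((len(cps), lattice.size), -np.inf)
    for k, c in enumerate(cps):
        p = null_eigenvector(model, c.x_star)
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(n > 0, n * np.log(p[:, None]), 0.0)
        terms = np.where((n > 0) & (p[:, None] == 0.0), -np.inf, terms)
        logs[k] = -np.log(len(cps)) + log_base + terms.sum(axis=0)
    logw = logsumexp(logs, axis=0)
    prob = np.exp(logw - logsumexp(logw))
    return LatticeDistribution.from_weights(lattice, prob)
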