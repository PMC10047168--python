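"""State-graph models with density-dependent rates.

A model is a finite set of M states ("chemical species", graph nodes) together
with a rate function pi(x): for a density vector x on the simplex, pi(x)[i, j]
is the transition rate of a particle from state j to state i.  The graph
Laplacian L(x) = diag(d(x)) - pi(x), with d_k the total out-rate of node k,
governs both the deterministic density flow dx/dt = -L(x) x and, through its
null right-eigenvector p(x), the Random Walk Approximation of the stationary
particle distribution.

This module provides the Laplacian, its null eigenvector, the deterministic
flow, the (simplex-tangent) Jacobian of p, self-consistent critical points
p(x*) = x*, and the spectral bifurcation diagnostic: a critical point loses
stability exactly when an eigenvalue of dp/dx crosses 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import scipy.linalg
import scipy.optimize

from .exceptions import (
    BoundaryDerivativeError,
    DisconnectedGraphError,
    InvalidModelError,
    NoCriticalPointError,
)

__all__ = [
    "StateGraphModel",
    "CriticalPoint",
    "ScanResult",
    "rate_matrix",
    "laplacian",
    "null_eigenvector",
    "null_eigenvector_many",
    "deterministic_rhs",
    "jacobian_p",
    "find_critical_points",
    "bifurcation_scan",
    "check_simplex",
]

#: eigenvalues of dp/dx within this distance of 1 are flagged "marginal"
STABILITY_MARGIN = 1e-9


@dataclass(frozen=True)
class StateGraphModel:
    """A finite state graph with density-dependent transition rates.

    Parameters
    ----------
    M : int
        Number of states (graph nodes).
    rates : callable
        Maps a length-M density vector x (on the simplex) to an (M, M)
        nonnegative matrix whose (i, j) entry is the rate j -> i, in units of
        inverse rescaled time.  Diagonal entries are ignored.  Rates depend on
        densities only, never on the particle number N.
    params : dict
        Named real parameters, kept for provenance.
    name : str
        Model label.
    rates_many : callable, optional
        Vectorized form: maps an (M, K) array of density columns to an
        (M, M, K) rate array.  Used for fast lattice-wide evaluation; must
        agree with ``rates`` column by column.
    """

    M: int
    rates: Callable[[np.ndarray], np.ndarray]
    params: dict = field(default_factory=dict)
    name: str = "model"
    rates_many: Callable[[np.ndarray], np.ndarray] | None = None

    def __post_init__(self):
        if self.M < 2:
            raise InvalidModelError("a state graph needs at least 2 states")


@dataclass(frozen=True)
class CriticalPoint:
    """A self-consistent density p(x*) = x* with its stability classification.

    ``stable`` is True iff every eigenvalue of dp/dx at x* has real part
    below 1 (strictly, with a 1e-9 guard band); eigenvalues within the guard
    band of 1 set ``marginal``.
    """

    x_star: np.ndarray
    jacobian_eigenvalues: np.ndarray
    stable: bool
    marginal: bool = False

    @property
    def spectral_indicator(self) -> float:
        """Largest real part among the eigenvalues of dp/dx (crosses 1 at a bifurcation)."""
        return float(np.max(self.jacobian_eigenvalues.real))


def check_simplex(x: np.ndarray, atol: float = 1e-9) -> np.ndarray:
    """Validate and return a density vector (entries in [0,1], summing to 1)."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("density vector must be one-dimensional")
    if np.any(x < -atol) or np.any(x > 1 + atol):
        raise ValueError(f"density vector outside [0,1]: {x}")
    if abs(x.sum() - 1.0) > 1e-9:
        raise ValueError(f"density vector must sum to 1, got {x.sum()!r}")
    return x


def rate_matrix(model: StateGraphModel, x: np.ndarray) -> np.ndarray:
    """Evaluate the model's rate matrix at x, zeroing the diagonal.

    Raises
    ------
    InvalidModelError
        If any off-diagonal rate is negative or non-finite.
    """
    pi = np.array(model.rates(np.asarray(x, dtype=float)), dtype=float)
    if pi.shape != (model.M, model.M):
        raise InvalidModelError(
            f"rates must return an ({model.M}, {model.M}) matrix, got {pi.shape}"
        )
    np.fill_diagonal(pi, 0.0)
    if not np.all(np.isfinite(pi)) or np.any(pi < 0):
        raise InvalidModelError(f"negative or non-finite rate at x={x}")
    return pi


def laplacian(model: StateGraphModel, x: np.ndarray) -> np.ndarray:
    """Graph Laplacian L(x) = diag(d(x)) - pi(x), d_k = sum_i pi_ik.

    Every column of L sums to 0 (probability-flux conservation).
    """
    pi = rate_matrix(model, x)
    d = pi.sum(axis=0)  # total out-rate of each node (column sums of pi)
    return np.diag(d) - pi


def _is_three_state_chain(pi: np.ndarray) -> bool:
    # A-B-C chain: no direct A<->C transitions
    return pi.shape == (3, 3) and pi[0, 2] == 0.0 and pi[2, 0] == 0.0


def _chain_null_vector(pi: np.ndarray) -> np.ndarray | None:
    """Closed-form null eigenvector for a 3-state A-B-C chain.

    p_A : p_B : p_C = pi_AB pi_BC : pi_BA pi_BC : pi_CB pi_BA.
    Returns None when the closed form degenerates (zero denominator).
    """
    pAB, pBA, pCB, pBC = pi[0, 1], pi[1, 0], pi[2, 1], pi[1, 2]
    w = np.array([pAB * pBC, pBA * pBC, pCB * pBA])
    s = w.sum()
    if s <= 0:
        return None
    return w / s


def null_eigenvector(model: StateGraphModel, x: np.ndarray) -> np.ndarray:
    """Null right-eigenvector p of L(x): L p = 0, p >= 0, sum(p) = 1.

    For 3-state chain models (no direct A<->C link) the closed form is used;
    otherwise the dense eigenproblem is solved and the eigenvector of the
    smallest-magnitude eigenvalue is taken, sign-fixed, clipped and
    renormalized (Perron-Frobenius guarantees nonnegativity for strongly
    connected graphs).

    Raises
    ------
    DisconnectedGraphError
        If the null space has dimension > 1 (graph not strongly connected).
    """
    pi = rate_matrix(model, x)
    if _is_three_state_chain(pi):
        p = _chain_null_vector(pi)
        if p is not None:
            return p
    L = np.diag(pi.sum(axis=0)) - pi
    vals, vecs = scipy.linalg.eig(L)
    order = np.argsort(np.abs(vals))
    scale = max(np.abs(vals).max(), 1.0)
    if len(vals) > 1 and np.abs(vals[order[1]]) < 1e-10 * scale:
        raise DisconnectedGraphError(
            "Laplacian null space is degenerate; the rate graph is not strongly connected"
        )
    p = vecs[:, order[0]].real
    if p.sum() < 0:
        p = -p
    if np.any(p < -1e-9):
        raise DisconnectedGraphError(
            "null eigenvector has significant negative entries; graph may be disconnected"
        )
    p = np.clip(p, 0.0, None)
    p = p / p.sum()
    if np.max(np.abs(L @ p)) > 1e-10 * scale:
        raise DisconnectedGraphError("null eigenvector residual too large")
    return p


def null_eigenvector_many(model: StateGraphModel, X: np.ndarray) -> np.ndarray:
    """Null eigenvector of L at every density column of X, shape (M, K) -> (M, K).

    Uses the vectorized closed form when the model supplies ``rates_many`` and
    is a 3-state chain; otherwise falls back to a per-column solve.
    """
    X = np.asarray(X, dtype=float)
    if model.rates_many is not None and model.M == 3:
        pi = np.asarray(model.rates_many(X), dtype=float)  # (3, 3, K)
        if np.any(pi[[0, 2], [2, 0], :] != 0):
            pass  # not a chain; fall through to the loop
        else:
            if np.any(pi < -1e-15):
                raise InvalidModelError("negative rate in vectorized evaluation")
            w = np.empty_like(X)
            w[0] = pi[0, 1] * pi[1, 2]
            w[1] = pi[1, 0] * pi[1, 2]
            w[2] = pi[2, 1] * pi[1, 0]
            s = w.sum(axis=0)
            ok = s > 0
            if np.all(ok):
                return w / s
            out = np.empty_like(X)
            out[:, ok] = w[:, ok] / s[ok]
            for k in np.nonzero(~ok)[0]:
                out[:, k] = null_eigenvector(model, X[:, k])
            return out
    return np.column_stack([null_eigenvector(model, X[:, k]) for k in range(X.shape[1])]).reshape(
        model.M, -1
    )


def deterministic_rhs(model: StateGraphModel, x: np.ndarray) -> np.ndarray:
    """Deterministic density flow dx/dt = -L(x) x; components sum to 0."""
    x = np.asarray(x, dtype=float)
    return -laplacian(model, x) @ x


def _reference_index(M: int) -> int:
    # the dependent simplex coordinate: the middle (B) state for 3-state
    # models, the last state otherwise
    return 1 if M == 3 else M - 1


def jacobian_p(
    model: StateGraphModel,
    x: np.ndarray,
    h: float = 1e-6,
    ref: int | None = None,
) -> np.ndarray:
    """Finite-difference matrix J with J[i, k] = dp_k/dx_i along simplex tangents.

    The derivative in coordinate i is taken along e_i - e_ref (increment x_i,
    decrement the reference coordinate), so x stays on the simplex; the row of
    the reference coordinate is identically 0.  Every row sums to 0 because p
    is normalized.  Stability/bifurcation tests use the eigenvalues of this
    matrix (invariant under transposition, so the dp/dx vs (dp/dx)^T
    convention does not matter).
    """
    x = np.asarray(x, dtype=float)
    M = model.M
    if ref is None:
        ref = _reference_index(M)
    J = np.zeros((M, M))
    for i in range(M):
        if i == ref:
            continue
        d = np.zeros(M)
        d[i], d[ref] = 1.0, -1.0
        xp, xm = x + h * d, x - h * d
        if np.any(xp < -1e-12) or np.any(xm < -1e-12) or np.any(xp > 1 + 1e-12) or np.any(xm > 1 + 1e-12):
            raise BoundaryDerivativeError(
                f"finite-difference step of size {h} leaves the simplex at x={x}"
            )
        J[i] = (null_eigenvector(model, xp) - null_eigenvector(model, xm)) / (2 * h)
    return J


def _assemble(z: np.ndarray, M: int, ref: int) -> np.ndarray:
    """Embed reduced coordinates (all but the reference one) into a density vector."""
    x = np.empty(M)
    kept = [i for i in range(M) if i != ref]
    x[kept] = z
    x[ref] = 1.0 - z.sum()
    return x


def _classify(model: StateGraphModel, x_star: np.ndarray) -> CriticalPoint:
    try:
        eigs = np.linalg.eigvals(jacobian_p(model, x_star))
    except BoundaryDerivativeError:
        # critical point on the simplex boundary: dp/dx undefined there
        return CriticalPoint(
            x_star=x_star, jacobian_eigenvalues=np.array([np.nan]), stable=False, marginal=False
        )
    top = np.max(eigs.real)
    marginal = abs(top - 1.0) <= STABILITY_MARGIN
    stable = top < 1.0 - STABILITY_MARGIN
    return CriticalPoint(x_star=x_star, jacobian_eigenvalues=eigs, stable=stable, marginal=marginal)


def _simplex_starts(M: int, n_starts: int, seed: int) -> list[np.ndarray]:
    rng = np.random.default_rng(seed)
    starts = [np.full(M, 1.0 / M)]
    if M == 3:
        # coarse triangular grid over the interior of the simplex
        for a in (0.1, 0.3, 0.5, 0.7, 0.9):
            for c in (0.1, 0.3, 0.5, 0.7, 0.9):
                if a + c < 0.95:
                    starts.append(np.array([a, 1.0 - a - c, c]))
    while len(starts) < max(n_starts, len(starts)):
        starts.append(rng.dirichlet(np.ones(M)))
    return starts[: max(n_starts, 26) if M == 3 else n_starts]


def find_critical_points(
    model: StateGraphModel,
    n_starts: int = 16,
    seed: int = 0,
    residual_tol: float = 1e-9,
) -> list[CriticalPoint]:
    """Self-consistent critical densities p(x*) = x*, deduplicated and classified.

    Multi-start root finding on the reduced simplex coordinates (all
    coordinates except the reference one, which is eliminated through the
    normalization constraint).  Starts are a fixed interior grid plus seeded
    Dirichlet draws.  Duplicates are merged when ||dx||_inf < 1e-6.

    Raises
    ------
    NoCriticalPointError
        If no start converges to a valid simplex fixed point.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    M, ref = model.M, _reference_index(model.M)

    def objective(z):
        x = _assemble(z, M, ref)
        if np.any(x < -0.2) or np.any(x > 1.2):
            return np.full(M - 1, 1e3)
        try:
            p = null_eigenvector(model, np.clip(x, 0.0, None) / max(np.clip(x, 0.0, None).sum(), 1e-12))
        except (InvalidModelError, DisconnectedGraphError):
            return np.full(M - 1, 1e3)
        kept = [i for i in range(M) if i != ref]
        return p[kept] - z

    roots: list[np.ndarray] = []
    kept = [i for i in range(M) if i != ref]
    for x0 in _simplex_starts(M, n_starts, seed):
        sol = scipy.optimize.root(objective, x0[kept], method="hybr", tol=1e-12)
        if not sol.success:
            continue
        x = _assemble(sol.x, M, ref)
        if np.any(x < -1e-9) or np.any(x > 1 + 1e-9):
            continue
        x = np.clip(x, 0.0, None)
        x = x / x.sum()
        try:
            res = np.abs(null_eigenvector(model, x) - x).sum()
        except DisconnectedGraphError:
            continue
        if res >= residual_tol:
            continue
        if not any(np.max(np.abs(x - r)) < 1e-6 for r in roots):
            roots.append(x)
    if not roots:
        raise NoCriticalPointError(f"no self-consistent density found for model {model.name!r}")
    roots.sort(key=lambda r: tuple(r))
    return [_classify(model, x) for x in roots]


@dataclass
class ScanResult:
    """Outcome of a bifurcation scan: the per-parameter spectral indicator and the refined crossing."""

    table: "pandas.DataFrame"  # noqa: F821 - imported lazily
    crossing: float | None


def _track_fixed_point(model: StateGraphModel, x_prev: np.ndarray) -> np.ndarray:
    """Continue a fixed point of x -> p(x) from a nearby previous solution."""
    M, ref = model.M, _reference_index(model.M)
    kept = [i for i in range(M) if i != ref]

    def objective(z):
        x = _assemble(z, M, ref)
        xc = np.clip(x, 0.0, None)
        p = null_eigenvector(model, xc / xc.sum())
        return p[kept] - z

    sol = scipy.optimize.root(objective, x_prev[kept], method="hybr", tol=1e-13)
    x = _assemble(sol.x, M, ref)
    x = np.clip(x, 0.0, None)
    return x / x.sum()


def bifurcation_scan(
    model_family: Callable[[float], StateGraphModel],
    param_grid: Sequence[float],
    refine_tol: float = 1e-6,
) -> ScanResult:
    """Scan a model family for loss of stability of the continued critical point.

    For each parameter value the critical point continued from the previous
    one is located and the largest real eigenvalue of dp/dx recorded; a
    bifurcation of the followed branch occurs where this indicator crosses 1
    (equivalently, where delta_ik - dp_i/dx_k acquires a null eigenvalue).
    The first crossing on the grid is refined by bisection to ``refine_tol``
    in the parameter.

    Returns a :class:`ScanResult` with a (param, indicator) table and the
    refined crossing (None, with a warning, if the indicator never crosses 1).
    """
    import pandas as pd

    grid = list(param_grid)
    if any(b < a for a, b in zip(grid, grid[1:])):
        raise ValueError("param_grid must be sorted ascending")

    model0 = model_family(grid[0])
    cps = find_critical_points(model0)
    stable = [c for c in cps if c.stable]
    x = (stable[0] if stable else cps[0]).x_star

    def indicator_at(param, x_start):
        model = model_family(param)
        x_fix = _track_fixed_point(model, x_start)
        eigs = np.linalg.eigvals(jacobian_p(model, x_fix))
        return float(np.max(eigs.real)), x_fix

    rows = []
    xs = []
    for param in grid:
        ind, x = indicator_at(param, x)
        rows.append((param, ind))
        xs.append(x)
    table = pd.DataFrame(rows, columns=["param", "indicator"])

    crossing = None
    for k in range(len(grid) - 1):
        lo, hi = rows[k], rows[k + 1]
        if lo[1] < 1.0 <= hi[1]:
            a, b = lo[0], hi[0]
            xa = xs[k]
            while b - a > refine_tol:
                mid = 0.5 * (a + b)
                ind, xm = indicator_at(mid, xa)
                if ind < 1.0:
                    a, xa = mid, xm
                else:
                    b = mid
            crossing = 0.5 * (a + b)
            break
    if crossing is None:
        warnings.warn("spectral indicator never crosses 1 on the scanned grid", stacklevel=2)
    return ScanResult(table=table, crossing=crossing)
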