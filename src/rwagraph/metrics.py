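"""Distances between lattice distributions: l1, Jensen-Shannon (base 2), covariance error."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import rel_entr

from .exceptions import LatticeMismatchError
from .lattice import LatticeDistribution, local_modes, moments

__all__ = [
    "ComparisonReport",
    "l1_distance",
    "js_divergence",
    "js_distance",
    "covariance_error",
    "modes_match",
    "compare",
]

_LN2 = np.log(2.0)


@dataclass
class ComparisonReport:
    """Distances of an approximate distribution from a reference one.

    l1 in [0, 2], js in [0, 1] (base-2 Jensen-Shannon divergence, so 1 is
    the maximum), cov_error the Frobenius norm of the covariance difference
    divided by N, and modes_match whether the two distributions place the
    same lattice modes.
    """

    method: str
    reference: str
    l1: float
    js: float
    cov_error: float
    modes_match: bool


def _check_same_lattice(p: LatticeDistribution, q: LatticeDistribution) -> None:
    if p.lattice.N != q.lattice.N or p.lattice.M != q.lattice.M:
        raise LatticeMismatchError(
            f"distributions on different lattices: (N={p.lattice.N}, M={p.lattice.M}) "
            f"vs (N={q.lattice.N}, M={q.lattice.M})"
        )


def l1_distance(p: LatticeDistribution, q: LatticeDistribution) -> float:
    """Total l1 distance sum |p - q| (equals twice the total variation, in [0, 2])."""
    _check_same_lattice(p, q)
    return float(np.abs(p.prob - q.prob).sum())


def js_divergence(p: LatticeDistribution, q: LatticeDistribution) -> float:
    """Jensen-Shannon divergence with base-2 logarithms, in [0, 1].

    JS(p, q) = KL(p || m)/2 + KL(q || m)/2 with m = (p + q)/2; states with
    zero probability contribute 0 (0 log 0 = 0 convention).
    """
    _check_same_lattice(p, q)
    m = 0.5 * (p.prob + q.prob)
    js = 0.5 * (rel_entr(p.prob, m).sum() + rel_entr(q.prob, m).sum()) / _LN2
    return float(min(max(js, 0.0), 1.0))


def js_distance(p: LatticeDistribution, q: LatticeDistribution) -> float:
    """Jensen-Shannon distance: the square root of the base-2 JS divergence.

    This is the metric (it satisfies the triangle inequality, unlike the
    divergence) and the scale on which headline percentage errors between
    stationary distributions are reported.
    """
    return float(np.sqrt(js_divergence(p, q)))


def covariance_error(p: LatticeDistribution, q: LatticeDistribution) -> float:
    """Frobenius norm of the difference of the n-covariance matrices, divided by N.

    The 1/N scaling makes the comparison scale-free across particle numbers
    (multinomial covariances grow linearly in N).
    """
    _check_same_lattice(p, q)
    _, cov_p = moments(p)
    _, cov_q = moments(q)
    return float(np.linalg.norm(cov_p - cov_q, "fro") / p.lattice.N)


def modes_match(p: LatticeDistribution, q: LatticeDistribution, tol_states: int = 2) -> bool:
    """Whether the two distributions have the same number of lattice modes, pairwise
    within ``tol_states`` (inf-norm on occupation numbers)."""
    _check_same_lattice(p, q)
    mp = [p.lattice.states[k] for k in local_modes(p)]
    mq = [q.lattice.states[k] for k in local_modes(q)]
    if len(mp) != len(mq):
        return False
    unmatched = list(mq)
    for a in mp:
        hit = next(
            (k for k, b in enumerate(unmatched) if np.max(np.abs(a - b)) <= tol_states), None
        )
        if hit is None:
            return False
        unmatched.pop(hit)
    return True


def compare(
    method_dist: LatticeDistribution,
    reference_dist: LatticeDistribution,
    method: str = "method",
    reference: str = "reference",
) -> ComparisonReport:
    """Full comparison report (l1, JS, covariance error, mode agreement)."""
    return ComparisonReport(
        method=method,
        reference=reference,
        l1=l1_distance(method_dist, reference_dist),
        js=js_divergence(method_dist, reference_dist),
        cov_error=covariance_error(method_dist, reference_dist),
        modes_match=modes_match(method_dist, reference_dist),
    )
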