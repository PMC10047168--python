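"""Enumeration of the conserved-N state space and the shared distribution container.

The network state is an occupation vector n = (n_1, ..., n_M) of nonnegative
integers with |n| = sum_i n_i = N fixed (microcanonical ensemble).  All
methods in this package (RWA, exact master-equation solvers, SSE, multinomial)
produce probability vectors over this lattice, held in
:class:`LatticeDistribution`.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np

from .exceptions import LatticeMismatchError

__all__ = [
    "SimplexLattice",
    "LatticeDistribution",
    "enumerate_lattice",
    "moments",
    "local_modes",
]

_SIZE_GUARD = int(5e7)


@dataclass(frozen=True)
class SimplexLattice:
    """All occupation vectors n with sum N over M states, in lexicographic order.

    Ordering is lexicographic on (n_1, ..., n_{M-1}); n_M is implied by the
    conservation constraint.  ``states`` is an (size, M) integer array and
    ``index_of`` inverts the enumeration.
    """

    N: int
    M: int
    states: np.ndarray
    _index: dict

    @property
    def size(self) -> int:
        return self.states.shape[0]

    def index_of(self, n) -> int:
        """Position of state n in the enumeration."""
        try:
            return self._index[tuple(int(v) for v in n)]
        except KeyError:
            raise KeyError(f"state {tuple(n)} is not on the |n|={self.N} lattice") from None

    def index_array(self, states: np.ndarray) -> np.ndarray:
        """Vectorized index lookup for an (K, M) array of states."""
        idx = self._index
        return np.fromiter(
            (idx[tuple(row)] for row in states.tolist()), dtype=np.int64, count=len(states)
        )

    def densities(self) -> np.ndarray:
        """(size, M) array of densities x = n / N."""
        return self.states / self.N


def enumerate_lattice(N: int, M: int) -> SimplexLattice:
    """Enumerate all occupation vectors with |n| = N over M states.

    The lattice has binomial(N+M-1, M-1) states ((N+1)(N+2)/2 for M=3); a
    guard raises if this exceeds 5e7.
    """
    if N < 1 or M < 2:
        raise ValueError("need N >= 1 and M >= 2")
    size = comb(N + M - 1, M - 1)
    if size > _SIZE_GUARD:
        raise ValueError(f"lattice would have {size} states (> {_SIZE_GUARD})")

    out = np.empty((size, M), dtype=np.int64)
    row = 0

    def fill(prefix, remaining, depth):
        nonlocal row
        if depth == M - 1:
            out[row, :depth] = prefix
            out[row, depth] = remaining
            row += 1
            return
        for v in range(remaining + 1):
            fill(prefix + [v], remaining - v, depth + 1)

    fill([], N, 0)
    index = {tuple(s): k for k, s in enumerate(out.tolist())}
    return SimplexLattice(N=N, M=M, states=out, _index=index)


@dataclass
class LatticeDistribution:
    """A probability vector over a :class:`SimplexLattice`."""

    lattice: SimplexLattice
    prob: np.ndarray

    def __post_init__(self):
        self.prob = np.asarray(self.prob, dtype=float)
        if self.prob.shape != (self.lattice.size,):
            raise LatticeMismatchError(
                f"probability vector of length {self.prob.shape} does not match "
                f"lattice of size {self.lattice.size}"
            )
        if np.any(self.prob < -1e-12):
            raise ValueError("negative probabilities")
        self.prob = np.clip(self.prob, 0.0, None)
        s = self.prob.sum()
        if abs(s - 1.0) > 1e-9:
            raise ValueError(f"probabilities sum to {s!r}, not 1")
        self.prob = self.prob / s

    @classmethod
    def from_weights(cls, lattice: SimplexLattice, weights: np.ndarray) -> "LatticeDistribution":
        """Normalize a nonnegative weight vector into a distribution."""
        w = np.clip(np.asarray(weights, dtype=float), 0.0, None)
        s = w.sum()
        if s <= 0:
            raise ValueError("weights sum to zero")
        return cls(lattice=lattice, prob=w / s)

    def max_prob(self) -> float:
        """The lattice maximum rho_max of the distribution."""
        return float(self.prob.max())

    def to_tsv(self, path, metadata: dict | None = None) -> None:
        """Write a TSV table with columns n_1 ... n_M, probability.

        ``metadata`` entries are written as '# key = value' header lines.
        """
        with open(path, "w") as fh:
            for key, val in (metadata or {}).items():
                fh.write(f"# {key} = {val}\n")
            cols = "\t".join(f"n_{i + 1}" for i in range(self.lattice.M))
            fh.write(f"{cols}\tprobability\n")
            for n, p in zip(self.lattice.states, self.prob):
                fh.write("\t".join(str(int(v)) for v in n) + f"\t{p:.17g}\n")


def moments(dist: LatticeDistribution) -> tuple[np.ndarray, np.ndarray]:
    """Exact mean vector and (M, M) covariance matrix of n by direct summation."""
    states = dist.lattice.states.astype(float)
    mean = dist.prob @ states
    centered = states - mean
    cov = np.einsum("k,ki,kj->ij", dist.prob, centered, centered)
    return mean, cov


def _neighbor_pairs(lattice: SimplexLattice):
    """Index pairs (s, t) for every one-step move n -> n - e_j + e_i on the lattice."""
    M = lattice.M
    for i in range(M):
        for j in range(M):
            if i == j:
                continue
            src = np.nonzero(lattice.states[:, j] >= 1)[0]
            shifted = lattice.states[src].copy()
            shifted[:, j] -= 1
            shifted[:, i] += 1
            yield i, j, src, lattice.index_array(shifted)


def local_modes(dist: LatticeDistribution) -> list[int]:
    """Lattice indices of the local maxima of a distribution.

    A state is a candidate if its probability is >= that of every one-step
    neighbor (moves n -> n - e_j + e_i); candidates that are themselves
    neighbors (exact symmetric ties) are merged into a single mode, keeping
    the highest-probability member.
    """
    p = dist.prob
    is_mode = p > 0.0  # flat zero-probability plateaus are never modes
    for _, _, src, dst in _neighbor_pairs(dist.lattice):
        is_mode[src] &= p[src] >= p[dst]
    candidates = set(np.nonzero(is_mode)[0].tolist())
    # merge neighboring tied candidates
    adjacency: dict[int, set[int]] = {c: set() for c in candidates}
    for _, _, src, dst in _neighbor_pairs(dist.lattice):
        for s, t in zip(src.tolist(), dst.tolist()):
            if s in candidates and t in candidates:
                adjacency[s].add(t)
                adjacency[t].add(s)
    modes = []
    seen: set[int] = set()
    for c in sorted(candidates):
        if c in seen:
            continue
        stack, component = [c], []
        while stack:
            v = stack.pop()
            if v in seen:
                continue
            seen.add(v)
            component.append(v)
            stack.extend(adjacency[v] - seen)
        modes.append(max(component, key=lambda k: p[k]))
    return sorted(modes)
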