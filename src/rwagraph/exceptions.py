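"""Exception hierarchy for rwagraph."""


class RwagraphError(Exception):
    """Base class for all rwagraph errors."""


class InvalidModelError(RwagraphError):
    """A model returned an invalid (e.g. negative) rate."""


class DisconnectedGraphError(RwagraphError):
    """The rate graph is not strongly connected: the Laplacian null space is degenerate."""


class BoundaryDerivativeError(RwagraphError):
    """A finite-difference step left the simplex near its boundary."""


class NoCriticalPointError(RwagraphError):
    """Multi-start root finding found no self-consistent density."""


class UnstableExpansionPointError(RwagraphError):
    """The system size expansion was requested at an unstable critical point."""


class SingularLyapunovError(RwagraphError):
    """The drift matrix has an eigenvalue at 0 (at a bifurcation); the Lyapunov equation is singular."""


class ReducibleChainError(RwagraphError):
    """The master-equation generator has a degenerate null space (reducible chain)."""


class ConvergenceError(RwagraphError):
    """Time integration did not reach stationarity within the step budget.

    Carries the last residual as ``residual`` and the last state as ``last_state``.
    """

    def __init__(self, message, residual=None, last_state=None, trace=None):
        super().__init__(message)
        self.residual = residual
        self.last_state = last_state
        self.trace = trace


class LatticeMismatchError(RwagraphError):
    """Two lattice objects (or a distribution and a generator) do not share a lattice."""


class InsufficientDataError(RwagraphError):
    """A time series is too short for the requested fit."""
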