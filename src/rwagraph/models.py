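"""Built-in three-state models: a threshold toy model and the dual PdPC cycle.

Both models share the A <-> B <-> C chain topology (no direct A <-> C
transition) and an exact A <-> C exchange symmetry at their default
parameters, which makes their bifurcations pitchfork-like: a symmetric
critical point loses stability and two mirror-symmetric stable points appear.

Toy model
    pi_AB = pi_CB = 1, pi_BA = theta(x_A), pi_BC = theta(x_C) with
    theta(x) = 1 - alpha + alpha (1 - x)^2, alpha in [0, 1].  At alpha = 0
    all rates are 1 (linear); crowding a terminal state suppresses its exit
    rate toward B, and beyond a critical alpha (numerically in (0.8, 0.9))
    the symmetric state is unstable.

Dual PdPC (standard quasi-steady-state approximation)
    x_A, x_B, x_C are the un-, mono- and double-phosphorylated substrate
    fractions; each of the four Michaelis-Menten reactions contributes a
    density-dependent effective rate with constants k_i (MM constants) and
    v_i (maximal velocities).  With the defaults k1 = k4 = 0.1, k2 = k3 = 1,
    v1 = v4 = 1, v3 = v2, the kinase velocity v2 is the control parameter and
    the cycle turns bistable at v2 = 2.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import StateGraphModel, bifurcation_scan, deterministic_rhs

__all__ = [
    "ToyParams",
    "PdpcParams",
    "toy_model",
    "toy_critical_alpha",
    "pdpc_model",
    "pdpc_critical_points",
    "pdpc_bistability_threshold",
    "MODEL_FAMILIES",
    "make_model",
]


@dataclass(frozen=True)
class ToyParams:
    """Toy threshold model parameter: alpha in [0, 1]."""

    alpha: float = 0.4

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must lie in [0, 1], got {self.alpha}")


@dataclass(frozen=True)
class PdpcParams:
    """Dual PdPC sQSSA parameters: MM constants k1..k4 and maximal velocities v1..v4.

    Defaults follow the symmetric reduction k1 = k4 = 0.1, k2 = k3 = 1,
    v1 = v4 = 1, v3 = v2, with v2 the control parameter.
    """

    v2: float = 1.82
    k1: float = 0.1
    k2: float = 1.0
    k3: float | None = None
    k4: float | None = None
    v1: float = 1.0
    v3: float | None = None
    v4: float | None = None

    def __post_init__(self):
        object.__setattr__(self, "k3", self.k2 if self.k3 is None else self.k3)
        object.__setattr__(self, "k4", self.k1 if self.k4 is None else self.k4)
        object.__setattr__(self, "v3", self.v2 if self.v3 is None else self.v3)
        object.__setattr__(self, "v4", self.v1 if self.v4 is None else self.v4)
        for name in ("k1", "k2", "k3", "k4", "v1", "v2", "v3", "v4"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")


def _theta(x, alpha):
    return 1.0 - alpha + alpha * (1.0 - x) ** 2


def toy_model(params: ToyParams | float = ToyParams()) -> StateGraphModel:
    """Three-state threshold model: pi_AB = pi_CB = 1, pi_BA = theta(x_A), pi_BC = theta(x_C)."""
    if not isinstance(params, ToyParams):
        params = ToyParams(alpha=float(params))
    alpha = params.alpha

    def rates(x):
        pi = np.zeros((3, 3))
        pi[0, 1] = 1.0  # B -> A
        pi[2, 1] = 1.0  # B -> C
        pi[1, 0] = _theta(x[0], alpha)  # A -> B
        pi[1, 2] = _theta(x[2], alpha)  # C -> B
        return pi

    def rates_many(X):
        K = X.shape[1]
        pi = np.zeros((3, 3, K))
        pi[0, 1] = 1.0
        pi[2, 1] = 1.0
        pi[1, 0] = _theta(X[0], alpha)
        pi[1, 2] = _theta(X[2], alpha)
        return pi

    return StateGraphModel(
        M=3, rates=rates, params={"alpha": alpha}, name="toy", rates_many=rates_many
    )


def toy_critical_alpha(refine_tol: float = 1e-6) -> float:
    """Critical alpha where the symmetric fixed point of the toy model loses stability.

    Located by the spectral bifurcation criterion (largest eigenvalue of
    dp/dx crossing 1 along the continued symmetric branch), bisection-refined.
    """
    scan = bifurcation_scan(
        lambda a: toy_model(ToyParams(alpha=a)),
        param_grid=np.linspace(0.0, 1.0, 11),
        refine_tol=refine_tol,
    )
    if scan.crossing is None:
        raise RuntimeError("no bifurcation found for the toy model on alpha in [0, 1]")
    return scan.crossing


def pdpc_model(params: PdpcParams = PdpcParams()) -> StateGraphModel:
    """Dual phosphorylation/dephosphorylation cycle under the sQSSA.

    Effective transition rates (A=0 unphosphorylated, B=1 mono, C=2 double):

        pi_AB = k4 v2 / (k4 k2 + k4 x_B + k2 x_C)
        pi_BA = k3 v1 / (k1 k3 + k1 x_B + k3 x_A)
        pi_CB = k1 v3 / (k1 k3 + k1 x_B + k3 x_A)
        pi_BC = k2 v4 / (k2 k4 + k4 x_B + k2 x_C)
    """
    q = params
    pdict = {k: getattr(q, k) for k in ("k1", "k2", "k3", "k4", "v1", "v2", "v3", "v4")}

    def rates(x):
        xA, xB, xC = x[0], x[1], x[2]
        dAC = q.k4 * q.k2 + q.k4 * xB + q.k2 * xC
        dAB = q.k1 * q.k3 + q.k1 * xB + q.k3 * xA
        pi = np.zeros((3, 3))
        pi[0, 1] = q.k4 * q.v2 / dAC  # B -> A
        pi[1, 0] = q.k3 * q.v1 / dAB  # A -> B
        pi[2, 1] = q.k1 * q.v3 / dAB  # B -> C
        pi[1, 2] = q.k2 * q.v4 / dAC  # C -> B
        return pi

    def rates_many(X):
        xA, xB, xC = X[0], X[1], X[2]
        dAC = q.k4 * q.k2 + q.k4 * xB + q.k2 * xC
        dAB = q.k1 * q.k3 + q.k1 * xB + q.k3 * xA
        K = X.shape[1]
        pi = np.zeros((3, 3, K))
        pi[0, 1] = q.k4 * q.v2 / dAC
        pi[1, 0] = q.k3 * q.v1 / dAB
        pi[2, 1] = q.k1 * q.v3 / dAB
        pi[1, 2] = q.k2 * q.v4 / dAC
        return pi

    return StateGraphModel(M=3, rates=rates, params=pdict, name="pdpc", rates_many=rates_many)


def pdpc_critical_points(params: PdpcParams = PdpcParams()) -> list[np.ndarray]:
    """Analytic critical densities of the symmetric dual PdPC.

    The symmetric point

        x1* = (k1 v2, k2 v1, k1 v2) / (k2 v1 + 2 k1 v2)

    exists for every parameter choice.  When the bistability conditions

        [v2 - v1 (1 + k2)]^2 >= [2 k1 v2]^2,  v2 >= v1,  v2 >= v1 (1 + k2)

    all hold, two mirror points (x+, b, x-) and (x-, b, x+) appear, with
    b = k2 v1 / (v2 - v1) and x+- the roots of

        s^2 - S s + P = 0,  S = (v2 - v1 (1 + k2)) / (v2 - v1),
                            P = (k1 v2 / (v2 - v1))^2,

    whose discriminant S^2 - 4P is exactly the first condition above divided
    by (v2 - v1)^2.  A discriminant within 1e-12 of zero (the double root) is
    treated as the bifurcation point itself and only the symmetric point is
    returned.  Requires the symmetric reduction k3 = k2, k4 = k1, v3 = v2,
    v4 = v1.
    """
    q = params
    if not (q.k3 == q.k2 and q.k4 == q.k1 and q.v3 == q.v2 and q.v4 == q.v1):
        raise ValueError("analytic critical points require the symmetric parameter reduction")
    denom = q.k2 * q.v1 + 2 * q.k1 * q.v2
    s = q.k1 * q.v2 / denom
    points = [np.array([s, q.k2 * q.v1 / denom, s])]

    cond = (
        (q.v2 - q.v1 * (1 + q.k2)) ** 2 >= (2 * q.k1 * q.v2) ** 2
        and q.v2 >= q.v1
        and q.v2 >= q.v1 * (1 + q.k2)
    )
    if cond:
        b = q.k2 * q.v1 / (q.v2 - q.v1)
        S = (q.v2 - q.v1 * (1 + q.k2)) / (q.v2 - q.v1)
        P = (q.k1 * q.v2 / (q.v2 - q.v1)) ** 2
        disc = S * S - 4 * P
        if disc > 1e-12:
            r = np.sqrt(disc)
            x_hi, x_lo = (S + r) / 2, (S - r) / 2
            points.append(np.array([x_hi, b, x_lo]))
            points.append(np.array([x_lo, b, x_hi]))
    return points


def pdpc_bistability_threshold(params: PdpcParams = PdpcParams()) -> float:
    """Smallest v2 at which all three bistability conditions hold (other parameters fixed).

    With the binding inequality v2 - v1(1+k2) >= 2 k1 v2 (the branch
    compatible with v2 >= v1(1+k2)), the closed form is
    v2 = v1 (1 + k2) / (1 - 2 k1), for k1 < 1/2.
    """
    q = params
    if 2 * q.k1 >= 1:
        raise ValueError("no finite bistability threshold for k1 >= 1/2")
    return q.v1 * (1 + q.k2) / (1 - 2 * q.k1)


def _verify_critical(params: PdpcParams) -> None:
    model = pdpc_model(params)
    for x in pdpc_critical_points(params):
        if np.abs(deterministic_rhs(model, x)).max() > 1e-9:
            raise AssertionError("analytic critical point does not zero the flow")


MODEL_FAMILIES = {
    "toy": lambda **kw: toy_model(ToyParams(**kw)),
    "pdpc": lambda **kw: pdpc_model(PdpcParams(**kw)),
}


def make_model(name: str, **params) -> StateGraphModel:
    """Instantiate a registered model family ('toy' or 'pdpc') by name."""
    try:
        family = MODEL_FAMILIES[name]
    except KeyError:
        raise ValueError(f"unknown model {name!r}; known: {sorted(MODEL_FAMILIES)}") from None
    return family(**params)
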