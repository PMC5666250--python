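"""Equilibria, existence regimes, linear stability and bifurcation direction.

The gang-free equilibrium is

    E0 = (p*Lambda/(mu+theta), Lambda*(theta+mu*(1-p))/(mu*(theta+mu)), 0, 0)

and is locally asymptotically stable iff Rg < 1.  Gang-persistent
equilibria have G* > 0 solving the quadratic

    a*G*^2 + b*G* + c = 0,

with (for valid parameters) a < 0 whenever eta > 0, sign(b) = sign(eta -
eta*), and sign(c) = sign(Rg - 1).  The number of admissible roots falls
into the regimes of the existence theorem: for eta > eta* and
1 - Rg* < Rg < 1 two endemic states coexist with the stable gang-free
state (backward bifurcation and bistability); the smaller root is a
saddle, the larger an attractor.

Bifurcation direction at Rg = 1 is decided by the center-manifold
coefficient ``a_cm``, which changes sign exactly at eta = eta*; the
transversality coefficient ``b_cm`` is positive for all valid
parameters, so a_cm > 0 implies a backward (subcritical) bifurcation and
a_cm < 0 a forward one.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as _dc_replace

import numpy as np

from .model import Parameters, State, require_valid, rhs_array
from .thresholds import (
    beta_star,
    eta_star,
    gang_reproduction_number,
    rg_star,
)

__all__ = [
    "QuadraticCoefficients",
    "EquilibriumPoint",
    "ExistenceRegime",
    "BifurcationReport",
    "gang_free_equilibrium",
    "endemic_coefficients",
    "solve_endemic",
    "classify_existence",
    "jacobian",
    "assess_stability",
    "bifurcation_direction",
]

#: Admissibility floor on G*: smaller roots belong to the gang-free branch.
TOL_POS = 1e-10
#: Absolute tolerance on eigenvalue real parts for stability labelling.
TOL_EIG = 1e-9
#: Tolerance for boundary detection in regime classification.
TOL_BOUNDARY = 1e-12
#: Normalized-discriminant window treated as a tangent (double) root.
TOL_TANGENT = 1e-10


def gang_free_equilibrium(params: Parameters) -> State:
    """The unique equilibrium with G = C = 0."""
    q = require_valid(params)
    sn = q.p * q.Lambda / (q.mu + q.theta)
    sr = q.Lambda * (q.theta + q.mu * (1.0 - q.p)) / (q.mu * (q.theta + q.mu))
    return State(Sn=sn, Sr=sr, G=0.0, C=0.0)


@dataclass(frozen=True)
class QuadraticCoefficients:
    """Coefficients of the endemic quadratic a*G*^2 + b*G* + c = 0.

    ``disc`` is the raw discriminant b^2 - 4ac and ``disc_normalized``
    the equivalent normalized form Rg* + Rg - 1 (same sign; NaN when
    eta = 0 and the equation degenerates to linear).
    """

    a: float
    b: float
    c: float
    disc: float
    disc_normalized: float


def endemic_coefficients(params: Parameters) -> QuadraticCoefficients:
    q = require_valid(params)
    gang_block = (q.gamma + q.mu) * (q.theta + q.mu) + q.sigma1 * (
        q.gamma * q.nu * q.epsilon + q.theta + q.mu
    )
    a = -q.beta * q.eta * q.mu * gang_block
    b = q.beta * (
        q.eta * q.Lambda * (q.theta + q.mu * (1.0 - q.p)) * (q.mu + q.sigma1)
        - q.mu * (q.mu + q.gamma) * (q.mu + q.theta)
        - q.mu * q.sigma1 * (q.gamma * q.nu * q.epsilon + q.theta + q.mu)
    )
    rg = gang_reproduction_number(q)
    c = (
        q.mu
        * (q.theta + q.mu)
        * (q.mu * (q.gamma + q.mu + q.sigma2) + q.sigma1 * (q.gamma * q.epsilon + q.mu + q.sigma2))
        * (rg - 1.0)
    )
    disc = b * b - 4.0 * a * c
    disc_norm = (rg_star(q) + rg - 1.0) if q.eta > 0 else float("nan")
    return QuadraticCoefficients(a=a, b=b, c=c, disc=disc, disc_normalized=disc_norm)


@dataclass(frozen=True)
class EquilibriumPoint:
    """An equilibrium state with optional stability annotation.

    ``residual`` is max |rhs| at the point; ``eigenvalues`` and
    ``stability`` are filled in by :func:`assess_stability`.
    """

    state: State
    kind: str  # "gang_free" | "gang_persistent"
    residual: float
    eigenvalues: np.ndarray | None = None
    stability: str | None = None  # "stable" | "unstable" | "marginal"


def _lift_root(g: float, params: Parameters) -> EquilibriumPoint:
    """Back-substitute a positive root G* into the remaining compartments."""
    q = params
    c_star = q.gamma * g / (q.mu + q.sigma1)
    sn_star = (q.sigma1 * (q.gamma * g * q.nu * q.epsilon + q.Lambda * q.p) + q.Lambda * q.mu * q.p) / (
        (q.theta + q.mu) * (q.mu + q.sigma1)
    )
    sr_star = (
        q.mu * (q.gamma + q.mu + q.sigma2) + q.sigma1 * (q.gamma * q.epsilon + q.mu + q.sigma2)
    ) / (q.beta * (q.eta * g + 1.0) * (q.mu + q.sigma1))
    state = State(Sn=sn_star, Sr=sr_star, G=g, C=c_star)
    residual = float(np.max(np.abs(rhs_array(state.as_array(), q))))
    return EquilibriumPoint(state=state, kind="gang_persistent", residual=residual)


def solve_endemic(params: Parameters, tol_pos: float = TOL_POS) -> list[EquilibriumPoint]:
    """All admissible gang-persistent equilibria, sorted ascending in G*.

    Roots of the endemic quadratic (the linear equation when eta = 0)
    with G* > tol_pos and nonnegative lifted compartments.  An empty
    list is a valid result (no endemic state).  A tangent (double) root
    is reported once.
    """
    q = require_valid(params)
    coef = endemic_coefficients(q)
    roots: list[float]
    if q.eta == 0.0:
        # a = 0: linear equation b*G + c = 0, b < 0 for valid parameters
        roots = [-coef.c / coef.b] if coef.b != 0 else []
    elif abs(coef.disc_normalized) < TOL_TANGENT:
        roots = [-coef.b / (2.0 * coef.a)]
    elif coef.disc < 0:
        roots = []
    else:
        sq = float(np.sqrt(coef.disc))
        roots = [(-coef.b + sq) / (2.0 * coef.a), (-coef.b - sq) / (2.0 * coef.a)]
    points = [
        _lift_root(g, q)
        for g in sorted(roots)
        if g > tol_pos
    ]
    return [pt for pt in points if min(pt.state.Sn, pt.state.Sr, pt.state.C) >= 0.0]


@dataclass(frozen=True)
class ExistenceRegime:
    """Regime label of the endemic-existence theorem with witness roots.

    Labels: H1_unique (eta = 0, Rg > 1); H2i_unique (eta > eta*,
    Rg > 1); H2ii_unique (eta < eta*, Rg > 1); H2iii_two (eta > eta*,
    1 - Rg* < Rg < 1); H2iv_none (eta > eta*, Rg < 1 - Rg*); H2v_none
    (eta < eta*, Rg < 1).  ``boundary`` flags inputs lying on a case
    boundary within tolerance; such inputs receive the
    lower-multiplicity label.
    """

    label: str
    witnesses: tuple[float, ...]
    boundary: bool = False

    @property
    def predicted_roots(self) -> int:
        return {"H1_unique": 1, "H2i_unique": 1, "H2ii_unique": 1, "H2iii_two": 2}.get(self.label, 0)


def classify_existence(params: Parameters, tol: float = TOL_BOUNDARY) -> ExistenceRegime:
    """Label the endemic-existence regime from the theorem's conditions."""
    q = require_valid(params)
    rg = gang_reproduction_number(q)
    witnesses = tuple(pt.state.G for pt in solve_endemic(q))
    if q.eta <= tol:
        if rg > 1.0 + tol:
            return ExistenceRegime("H1_unique", witnesses)
        return ExistenceRegime("H2v_none", witnesses, boundary=abs(rg - 1.0) <= tol)
    eta_s = eta_star(q)
    if q.eta > eta_s + tol:
        if rg > 1.0 + tol:
            return ExistenceRegime("H2i_unique", witnesses)
        if abs(rg - 1.0) <= tol:
            # at Rg = 1 with eta > eta* the quadratic still has one positive root
            return ExistenceRegime("H2i_unique", witnesses, boundary=True)
        fold = 1.0 - rg_star(q)
        if rg > fold + tol:
            return ExistenceRegime("H2iii_two", witnesses)
        if rg < fold - tol:
            return ExistenceRegime("H2iv_none", witnesses)
        return ExistenceRegime("H2iv_none", witnesses, boundary=True)
    if q.eta < eta_s - tol:
        if rg > 1.0 + tol:
            return ExistenceRegime("H2ii_unique", witnesses)
        return ExistenceRegime("H2v_none", witnesses, boundary=abs(rg - 1.0) <= tol)
    # eta on the eta* boundary: b = 0, root count decided by sign of c
    if rg > 1.0 + tol:
        return ExistenceRegime("H2ii_unique", witnesses, boundary=True)
    return ExistenceRegime("H2v_none", witnesses, boundary=True)


def jacobian(params: Parameters, state: State) -> np.ndarray:
    """Exact Jacobian of the vector field at ``state``, (Sn, Sr, G, C) order."""
    q = require_valid(params)
    Sn, Sr, G, C = state.as_array()
    force_sr = q.beta * G * (1.0 + q.eta * G)        # d(force)/dSr
    force_g = q.beta * Sr * (1.0 + 2.0 * q.eta * G)  # d(force)/dG
    return np.array(
        [
            [-(q.mu + q.theta), 0.0, 0.0, q.nu * q.epsilon * q.sigma1],
            [q.theta, -force_sr - q.mu, q.sigma2 - force_g, (1.0 - q.nu) * q.epsilon * q.sigma1],
            [0.0, force_sr, force_g - (q.mu + q.sigma2 + q.gamma), (1.0 - q.epsilon) * q.sigma1],
            [0.0, 0.0, q.gamma, -(q.mu + q.sigma1)],
        ]
    )


def gang_free_quadratic_factor(params: Parameters) -> tuple[float, float]:
    """(linear, constant) coefficients of the nontrivial characteristic factor
    at the gang-free point: lambda^2 + (Q1+Q2-beta*Sr0)*lambda
    + (mu*Q2 + sigma1*Q3)*(1 - Rg), with Q1 = mu+sigma1, Q2 = mu+gamma+sigma2,
    Q3 = gamma*epsilon+mu+sigma2."""
    q = require_valid(params)
    Q1 = q.mu + q.sigma1
    Q2 = q.mu + q.gamma + q.sigma2
    Q3 = q.gamma * q.epsilon + q.mu + q.sigma2
    sr0 = gang_free_equilibrium(q).Sr
    rg = gang_reproduction_number(q)
    return (Q1 + Q2 - q.beta * sr0, (q.mu * Q2 + q.sigma1 * Q3) * (1.0 - rg))


def assess_stability(params: Parameters, point: EquilibriumPoint, tol_eig: float = TOL_EIG) -> EquilibriumPoint:
    """Label an equilibrium by the eigenvalues of the Jacobian.

    Stable iff every real part < -tol_eig, unstable iff some real part
    > tol_eig, marginal otherwise.  For the gang-free point the spectrum
    factorises as {-(mu+theta), -mu} plus a quadratic factor whose
    constant term is proportional to 1 - Rg, so stability is equivalent
    to Rg < 1.
    """
    eig = np.linalg.eigvals(jacobian(params, point.state))
    re = eig.real
    if np.all(re < -tol_eig):
        label = "stable"
    elif np.any(re > tol_eig):
        label = "unstable"
    else:
        label = "marginal"
    return _dc_replace(point, eigenvalues=eig, stability=label)


def gang_free_point(params: Parameters, assess: bool = True) -> EquilibriumPoint:
    """The gang-free equilibrium as an (optionally labelled) point."""
    state = gang_free_equilibrium(params)
    residual = float(np.max(np.abs(rhs_array(state.as_array(), params))))
    pt = EquilibriumPoint(state=state, kind="gang_free", residual=residual)
    return assess_stability(params, pt) if assess else pt


@dataclass(frozen=True)
class BifurcationReport:
    """Center-manifold diagnostics at the bifurcation point beta = beta*.

    ``w`` and ``v`` are the right and left null eigenvectors of the
    Jacobian at the gang-free point (closed forms, unnormalized — only
    the signs of the coefficients matter, and positive rescaling
    preserves them).  ``direction`` is "backward" iff a_cm > 0, which
    holds iff eta > eta*; b_cm > 0 always.
    """

    beta_star: float
    w: np.ndarray
    v: np.ndarray
    a_cm: float
    b_cm: float
    direction: str


def bifurcation_direction(params: Parameters) -> BifurcationReport:
    """Classify the bifurcation at Rg = 1, replacing beta by beta* internally."""
    q = require_valid(params)
    bstar = beta_star(q)
    w = np.array(
        [
            q.gamma * q.nu * q.sigma1 * q.epsilon,
            -((q.gamma + q.mu) * (q.theta + q.mu) + q.sigma1 * (q.gamma * q.nu * q.epsilon + q.theta + q.mu)),
            (q.theta + q.mu) * (q.mu + q.sigma1),
            q.gamma * (q.theta + q.mu),
        ]
    )
    v = np.array([0.0, 0.0, q.mu + q.sigma1, (1.0 - q.epsilon) * q.sigma1])
    eta_s = eta_star(q)
    a_cm = (
        2.0
        * q.Lambda
        * bstar
        * (q.mu + q.theta)
        * (q.theta + (1.0 - q.p) * q.mu)
        * (q.mu + q.sigma1) ** 3
        * (q.eta - eta_s)
        / q.mu
    )
    b_cm = q.Lambda * (q.mu + q.sigma1) ** 2 * (q.theta + q.mu * (1.0 - q.p)) / q.mu
    direction = "backward" if a_cm > 0 else "forward"
    return BifurcationReport(beta_star=bstar, w=w, v=v, a_cm=a_cm, b_cm=b_cm, direction=direction)
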