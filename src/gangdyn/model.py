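"""Core data model and vector field for gang dynamics with correctional services.

The population is partitioned into four compartments:

* ``Sn`` — susceptible individuals *not* at risk of joining a gang,
* ``Sr`` — susceptible individuals at risk of joining a gang,
* ``G``  — active gang members,
* ``C``  — individuals held in correctional services.

New entrants arrive at rate ``Lambda``; a proportion ``p`` enters the
not-at-risk class and ``1 - p`` the at-risk class.  Environmental change
moves people from ``Sn`` to ``Sr`` at rate ``theta``.  Initiation into
gangs is an imitation process with force

    f(Sr, G) = beta * G * (1 + eta * G) * Sr,

where ``beta`` is the effective contact rate and ``eta`` the imitation
coefficient amplifying peer influence.  Gang members quit voluntarily at
rate ``sigma2`` or are convicted and sentenced at rate ``gamma``.
Releases from correctional services occur at rate ``sigma1``; with
programme efficacy ``epsilon`` a released individual rejoins the
community (a proportion ``nu`` of effective releases returns to ``Sn``,
the rest to ``Sr``), while the ineffective fraction ``1 - epsilon``
reverts straight to the gang.  All compartments experience a natural
per-capita exit rate ``mu``.

The full system of ordinary differential equations is

    dSn/dt = p*Lambda + nu*epsilon*sigma1*C - (mu + theta)*Sn
    dSr/dt = (1-p)*Lambda + theta*Sn + sigma2*G + (1-nu)*epsilon*sigma1*C
             - beta*G*(1 + eta*G)*Sr - mu*Sr
    dG/dt  = beta*G*(1 + eta*G)*Sr + (1-epsilon)*sigma1*C
             - (mu + sigma2 + gamma)*G
    dC/dt  = gamma*G - (mu + sigma1)*C

so that the total population N = Sn + Sr + G + C obeys
dN/dt = Lambda - mu*N and the region {N <= Lambda/mu} is positively
invariant.  The canonical time unit is years.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields, replace

import numpy as np

__all__ = [
    "PARAMETER_NAMES",
    "COMPARTMENTS",
    "Parameters",
    "State",
    "Trajectory",
    "InvalidParametersError",
    "validate",
    "require_valid",
    "initiation_force",
    "rhs",
    "rhs_array",
]

#: Canonical parameter ordering, matching the external file schema.
PARAMETER_NAMES = (
    "Lambda",
    "mu",
    "p",
    "theta",
    "beta",
    "eta",
    "sigma1",
    "sigma2",
    "gamma",
    "epsilon",
    "nu",
)

#: Canonical compartment ordering used for vectors, Jacobians and files.
COMPARTMENTS = ("Sn", "Sr", "G", "C")

# Rates that must be strictly positive; eta is allowed to be zero
# (bilinear incidence) and p, nu, epsilon are proportions in [0, 1].
_STRICT_POSITIVE = ("Lambda", "mu", "theta", "beta", "sigma1", "sigma2", "gamma")
_PROPORTIONS = ("p", "nu", "epsilon")


class InvalidParametersError(ValueError):
    """Raised when a parameter set violates the model's domain constraints."""

    def __init__(self, violations: list[str]):
        self.violations = list(violations)
        super().__init__("; ".join(self.violations))


@dataclass(frozen=True)
class Parameters:
    """The eleven model rates and proportions.

    Units: ``Lambda`` individuals/year; ``mu``, ``theta``, ``sigma1``,
    ``sigma2``, ``gamma`` per year; ``beta`` per (individual * year);
    ``eta`` per individual; ``p``, ``epsilon``, ``nu`` dimensionless
    proportions in [0, 1].
    """

    Lambda: float
    mu: float
    p: float
    theta: float
    beta: float
    eta: float
    sigma1: float
    sigma2: float
    gamma: float
    epsilon: float
    nu: float

    def replace(self, **changes: float) -> "Parameters":
        return replace(self, **changes)

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def validate(params: Parameters) -> list[str]:
    """Check every domain constraint; return the list of violations.

    An empty list means the parameter set is valid.  Each entry names the
    offending field, so callers can surface actionable diagnostics.
    """
    violations: list[str] = []
    for name in PARAMETER_NAMES:
        value = getattr(params, name)
        if not isinstance(value, (int, float)) or not math.isfinite(value):
            violations.append(f"{name}: not a finite number ({value!r})")
            continue
        if name in _STRICT_POSITIVE and value <= 0:
            violations.append(f"{name}: must be strictly positive, got {value}")
        elif name == "eta" and value < 0:
            violations.append(f"eta: must be nonnegative, got {value}")
        elif name in _PROPORTIONS and not (0.0 <= value <= 1.0):
            violations.append(f"{name}: must lie in [0, 1], got {value}")
    return violations


def require_valid(params: Parameters) -> Parameters:
    """Return ``params`` unchanged or raise :class:`InvalidParametersError`."""
    violations = validate(params)
    if violations:
        raise InvalidParametersError(violations)
    return params


@dataclass(frozen=True)
class State:
    """Compartment occupancies (individuals) at one instant."""

    Sn: float
    Sr: float
    G: float
    C: float

    @property
    def N(self) -> float:
        """Total population, the exact component sum."""
        return self.Sn + self.Sr + self.G + self.C

    def as_array(self) -> np.ndarray:
        return np.array([self.Sn, self.Sr, self.G, self.C], dtype=float)

    @classmethod
    def from_array(cls, y: np.ndarray) -> "State":
        return cls(float(y[0]), float(y[1]), float(y[2]), float(y[3]))

    def require_nonnegative(self) -> "State":
        bad = [n for n, v in zip(COMPARTMENTS, self.as_array()) if v < 0]
        if bad:
            raise ValueError(f"negative compartment(s): {', '.join(bad)}")
        return self


@dataclass(frozen=True)
class Trajectory:
    """A solution sampled on a strictly increasing time grid.

    ``states`` has shape ``(len(times), 4)`` in the (Sn, Sr, G, C)
    ordering; ``N`` is the row sum.
    """

    times: np.ndarray
    states: np.ndarray

    def __post_init__(self):
        if self.states.shape != (len(self.times), 4):
            raise ValueError("states must have shape (len(times), 4)")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def Sn(self) -> np.ndarray:
        return self.states[:, 0]

    @property
    def Sr(self) -> np.ndarray:
        return self.states[:, 1]

    @property
    def G(self) -> np.ndarray:
        return self.states[:, 2]

    @property
    def C(self) -> np.ndarray:
        return self.states[:, 3]

    @property
    def N(self) -> np.ndarray:
        return self.states.sum(axis=1)

    def final_state(self) -> State:
        return State.from_array(self.states[-1])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "t": self.times,
                "Sn": self.Sn,
                "Sr": self.Sr,
                "G": self.G,
                "C": self.C,
                "N": self.N,
            }
        )


def initiation_force(Sr: float, G: float, params: Parameters) -> float:
    """Imitation-driven initiation rate f(Sr, G) = beta*G*(1 + eta*G)*Sr.

    Zero whenever there are no gang members or no at-risk susceptibles;
    monotone nondecreasing in both arguments on the nonnegative domain.
    """
    if Sr < 0 or G < 0:
        raise ValueError(f"initiation_force requires Sr >= 0 and G >= 0, got Sr={Sr}, G={G}")
    return params.beta * G * (1.0 + params.eta * G) * Sr


def rhs_array(y: np.ndarray, params: Parameters) -> np.ndarray:
    """Vector field on a raw (Sn, Sr, G, C) array; no validation.

    This is the hot path used by the integrator and by finite-difference
    Jacobian checks.
    """
    Sn, Sr, G, C = y
    q = params
    force = q.beta * G * (1.0 + q.eta * G) * Sr
    dSn = q.p * q.Lambda + q.nu * q.epsilon * q.sigma1 * C - (q.mu + q.theta) * Sn
    dSr = (
        (1.0 - q.p) * q.Lambda
        + q.theta * Sn
        + q.sigma2 * G
        + (1.0 - q.nu) * q.epsilon * q.sigma1 * C
        - force
        - q.mu * Sr
    )
    dG = force + (1.0 - q.epsilon) * q.sigma1 * C - (q.mu + q.sigma2 + q.gamma) * G
    dC = q.gamma * G - (q.mu + q.sigma1) * C
    return np.array([dSn, dSr, dG, dC])


def rhs(state: State, params: Parameters) -> np.ndarray:
    """Time derivatives (dSn/dt, dSr/dt, dG/dt, dC/dt) at ``state``.

    The component sum always equals Lambda - mu*N (mass balance).
    """
    require_valid(params)
    state.require_nonnegative()
    return rhs_array(state.as_array(), params)
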