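"""Closed-form threshold quantities and normalized forward sensitivity indices.

The central quantity is the gang reproduction number

    Rg = beta*Lambda*(mu+sigma1)*(theta+mu*(1-p))
         / [mu*(theta+mu)*(mu*(gamma+mu+sigma2) + sigma1*(gamma*epsilon+mu+sigma2))],

the expected number of initiations a single gang member produces in a
wholly susceptible population.  Setting epsilon = 0 (no rehabilitative
effect of correctional services) gives the basic reproduction number R0.
Derived thresholds:

* ``epsilon_star`` — the programme efficacy at which Rg crosses 1 when
  R0 > 1 (may exceed 1, in which case no attainable efficacy suffices);
* ``beta_star``   — the contact rate at which Rg = 1;
* ``eta_star``    — the imitation coefficient above which the endemic
  quadratic's linear coefficient turns positive, the switch between
  forward and backward bifurcation at Rg = 1;
* ``Rg_star``     — the width parameter of the subcritical window: for
  eta > eta_star two endemic states coexist on 1 - Rg_star < Rg < 1.

Sensitivity is quantified by the normalized forward sensitivity index
(elasticity) of Rg with respect to a parameter q,

    Upsilon_q = (dRg/dq) * (q / Rg),

available both from the printed closed forms (``analytic``) and by
central finite differences (``numeric``).  The index with respect to mu
is provided numerically only; raising the natural exit rate is not a
policy lever, so no analytic form is exposed for it.
"""

from __future__ import annotations

from dataclasses import dataclass

from .model import Parameters, require_valid

__all__ = [
    "ThresholdReport",
    "SensitivityReport",
    "SENSITIVITY_PARAMETERS",
    "gang_reproduction_number",
    "basic_reproduction_number",
    "critical_efficacy",
    "eta_star",
    "rg_star",
    "beta_star",
    "sensitivity_index_analytic",
    "sensitivity_index_numeric",
    "threshold_report",
    "sensitivity_report",
    "sensitivity_table",
]

#: Parameters with a printed analytic elasticity of Rg.
SENSITIVITY_PARAMETERS = ("beta", "Lambda", "sigma1", "sigma2", "theta", "p", "gamma", "epsilon")


def _correction_denominator(q: Parameters) -> float:
    """mu*(gamma+mu+sigma2) + sigma1*(gamma*epsilon+mu+sigma2), the exit/
    relapse balance of the (G, C) subsystem; appears in every threshold."""
    return q.mu * (q.gamma + q.mu + q.sigma2) + q.sigma1 * (q.gamma * q.epsilon + q.mu + q.sigma2)


def _rg_formula(q: Parameters) -> float:
    # closed form without domain validation; lets callers probe the
    # algebraic identities (e.g. Rg at epsilon* > 1) outside [0, 1]
    num = q.beta * q.Lambda * (q.mu + q.sigma1) * (q.theta + q.mu * (1.0 - q.p))
    den = q.mu * (q.theta + q.mu) * _correction_denominator(q)
    return num / den


def gang_reproduction_number(params: Parameters) -> float:
    """Rg from its closed form."""
    return _rg_formula(require_valid(params))


def basic_reproduction_number(params: Parameters) -> float:
    """R0 = Rg evaluated at epsilon = 0 (dysfunctional correctional services)."""
    require_valid(params)
    return gang_reproduction_number(params.replace(epsilon=0.0))


@dataclass(frozen=True)
class CriticalEfficacy:
    """Threshold efficacy epsilon* with an attainability flag.

    ``value`` solves Rg(epsilon) = 1; it is negative when R0 < 1 (no
    correction needed) and exceeds 1 when even perfect correctional
    services cannot push Rg below one.  ``attainable`` is True iff
    value lies in [0, 1].
    """

    value: float
    attainable: bool


def critical_efficacy(params: Parameters) -> CriticalEfficacy:
    """epsilon* = [(mu*(mu+gamma+sigma2) + sigma1*(mu+sigma2)) / (gamma*sigma1)] * (R0 - 1)."""
    q = require_valid(params)
    if q.gamma == 0 or q.sigma1 == 0:
        raise ZeroDivisionError("epsilon* is singular when gamma = 0 or sigma1 = 0")
    r0 = basic_reproduction_number(q)
    factor = (q.mu * (q.mu + q.gamma + q.sigma2) + q.sigma1 * (q.mu + q.sigma2)) / (q.gamma * q.sigma1)
    value = factor * (r0 - 1.0)
    return CriticalEfficacy(value=value, attainable=0.0 <= value <= 1.0)


def eta_star(params: Parameters) -> float:
    """Imitation-coefficient threshold separating forward from backward bifurcation.

    eta* = [mu*(mu+gamma)*(mu+theta) + mu*sigma1*(gamma*nu*epsilon+theta+mu)]
           / [Lambda*(theta+mu*(1-p))*(mu+sigma1)]
    """
    q = require_valid(params)
    num = q.mu * (q.mu + q.gamma) * (q.mu + q.theta) + q.mu * q.sigma1 * (
        q.gamma * q.nu * q.epsilon + q.theta + q.mu
    )
    den = q.Lambda * (q.theta + q.mu * (1.0 - q.p)) * (q.mu + q.sigma1)
    return num / den


def rg_star(params: Parameters) -> float:
    """Subcritical-window width parameter Rg*.

    Defined for eta > 0; two endemic equilibria coexist exactly on
    1 - Rg* < Rg < 1 when eta > eta*.  Proportional to the square of the
    endemic quadratic's linear coefficient, so it vanishes at eta = eta*.
    """
    q = require_valid(params)
    if q.eta == 0:
        raise ZeroDivisionError("Rg* is undefined for eta = 0 (bilinear incidence)")
    x = (
        q.eta * q.Lambda * (q.theta + q.mu * (1.0 - q.p)) * (q.mu + q.sigma1)
        - q.mu * (q.mu + q.gamma) * (q.mu + q.theta)
        - q.mu * q.sigma1 * (q.gamma * q.nu * q.epsilon + q.theta + q.mu)
    )
    num = q.beta * x * x
    den = (
        4.0
        * q.mu**2
        * q.eta
        * (q.mu + q.theta)
        * ((q.gamma + q.mu) * (q.theta + q.mu) + q.sigma1 * (q.gamma * q.nu * q.epsilon + q.theta + q.mu))
        * _correction_denominator(q)
    )
    return num / den


def beta_star(params: Parameters) -> float:
    """Contact rate at which Rg = 1 (the bifurcation point)."""
    q = require_valid(params)
    num = q.mu * (q.theta + q.mu) * _correction_denominator(q)
    den = q.Lambda * (q.mu + q.sigma1) * (q.theta + q.mu * (1.0 - q.p))
    return num / den


def sensitivity_index_analytic(params: Parameters, q_name: str) -> float:
    """Printed closed-form elasticity of Rg with respect to ``q_name``.

    Supported parameters: beta, Lambda, sigma1, sigma2, theta, p, gamma,
    epsilon.  ``mu`` is deliberately unsupported here (use the numeric
    estimator); unknown names raise ``KeyError``.
    """
    q = require_valid(params)
    if q_name == "mu":
        raise ValueError("no analytic index is exposed for mu; use sensitivity_index_numeric")
    if q_name not in SENSITIVITY_PARAMETERS:
        raise KeyError(f"unknown sensitivity parameter {q_name!r}; choose from {SENSITIVITY_PARAMETERS}")
    den = _correction_denominator(q)
    if q_name == "beta" or q_name == "Lambda":
        return 1.0
    if q_name == "sigma1":
        return (q.gamma * q.mu * q.sigma1 * (1.0 - q.epsilon)) / ((q.mu + q.sigma1) * den)
    if q_name == "sigma2":
        return -q.sigma2 * (q.mu + q.sigma1) / den
    if q_name == "theta":
        return (q.theta * q.mu * q.p) / ((q.theta + q.mu) * (q.theta + q.mu * (1.0 - q.p)))
    if q_name == "p":
        return -q.mu * q.p / (q.theta + q.mu * (1.0 - q.p))
    if q_name == "gamma":
        return -q.gamma * (q.mu + q.sigma1 * q.epsilon) / den
    # epsilon
    return -q.gamma * q.sigma1 * q.epsilon / den


def sensitivity_index_numeric(params: Parameters, q_name: str, rel_step: float = 1e-6) -> float:
    """Central finite-difference estimate of (dRg/dq) * (q/Rg).

    Any of the eight analytic parameters plus ``mu`` is accepted.  If a
    perturbed value leaves the valid domain the step is halved once; a
    second failure raises.  A parameter currently equal to zero has a
    zero elasticity by definition and is returned as such.
    """
    q = require_valid(params)
    if q_name not in SENSITIVITY_PARAMETERS and q_name != "mu":
        raise KeyError(f"unknown sensitivity parameter {q_name!r}")
    if not (0.0 < rel_step <= 1e-2):
        raise ValueError(f"rel_step must lie in (0, 1e-2], got {rel_step}")
    value = getattr(q, q_name)
    if value == 0.0:
        return 0.0
    rg = gang_reproduction_number(q)
    for step in (rel_step * abs(value), 0.5 * rel_step * abs(value)):
        hi = q.replace(**{q_name: value + step})
        lo = q.replace(**{q_name: value - step})
        from .model import validate as _validate

        if _validate(hi) or _validate(lo):
            continue
        deriv = (gang_reproduction_number(hi) - gang_reproduction_number(lo)) / (2.0 * step)
        return deriv * value / rg
    raise ValueError(
        f"cannot perturb {q_name}={value} by a central step without leaving the valid domain"
    )


@dataclass(frozen=True)
class ThresholdReport:
    """All closed-form threshold quantities for one parameter set."""

    Rg: float
    R0: float
    epsilon_star: float
    epsilon_star_attainable: bool
    eta_star: float
    Rg_star: float | None
    beta_star: float

    def as_dict(self) -> dict:
        return {
            "Rg": self.Rg,
            "R0": self.R0,
            "epsilon_star": self.epsilon_star,
            "epsilon_star_attainable": self.epsilon_star_attainable,
            "eta_star": self.eta_star,
            "Rg_star": self.Rg_star,
            "beta_star": self.beta_star,
        }


def threshold_report(params: Parameters) -> ThresholdReport:
    """Evaluate every threshold quantity; Rg* is None when eta = 0."""
    q = require_valid(params)
    eff = critical_efficacy(q)
    return ThresholdReport(
        Rg=gang_reproduction_number(q),
        R0=basic_reproduction_number(q),
        epsilon_star=eff.value,
        epsilon_star_attainable=eff.attainable,
        eta_star=eta_star(q),
        Rg_star=rg_star(q) if q.eta > 0 else None,
        beta_star=beta_star(q),
    )


@dataclass(frozen=True)
class SensitivityReport:
    """Signed elasticities of Rg, one per supported parameter."""

    indices: dict[str, float]
    method: str  # "analytic" | "numeric"


def sensitivity_report(params: Parameters, method: str = "analytic", rel_step: float = 1e-6) -> SensitivityReport:
    if method == "analytic":
        values = {name: sensitivity_index_analytic(params, name) for name in SENSITIVITY_PARAMETERS}
    elif method == "numeric":
        values = {
            name: sensitivity_index_numeric(params, name, rel_step=rel_step)
            for name in SENSITIVITY_PARAMETERS
        }
    else:
        raise ValueError(f"method must be 'analytic' or 'numeric', got {method!r}")
    return SensitivityReport(indices=values, method=method)


def sensitivity_table(params: Parameters, rel_step: float = 1e-6):
    """Side-by-side analytic and numeric elasticities as a DataFrame.

    Columns: parameter, analytic_index, numeric_index, abs_diff.
    """
    import pandas as pd

    analytic = sensitivity_report(params, "analytic").indices
    numeric = sensitivity_report(params, "numeric", rel_step=rel_step).indices
    rows = [
        {
            "parameter": name,
            "analytic_index": analytic[name],
            "numeric_index": numeric[name],
            "abs_diff": abs(analytic[name] - numeric[name]),
        }
        for name in SENSITIVITY_PARAMETERS
    ]
    return pd.DataFrame(rows)
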