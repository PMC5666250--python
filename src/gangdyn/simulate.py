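"""Time integration and scenario studies: sweeps, contours, bifurcation diagrams.

Integration uses an adaptive explicit Runge–Kutta scheme (DOP853) with
tight defaults (rtol 1e-8, atol 1e-10) sampled on a uniform output grid.
The vector field preserves the nonnegative orthant and the region
N <= Lambda/mu; tiny numerical undershoots below zero (within
max(atol, rtol * population scale)) are clamped to zero on output with a
logged warning, anything more negative aborts with a diagnostic.

Scenario helpers mirror the standard policy questions for this model:
how the gang compartment at a fixed horizon responds to the efficacy
``epsilon`` or the conviction rate ``gamma``, how Rg varies over a
(sigma2, gamma) grid, the fold structure of the bifurcation diagram in
the backward regime, and the dependence of the long-run outcome on the
initial gang size (hysteresis).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .model import Parameters, State, Trajectory, require_valid, rhs_array
from .equilibria import assess_stability, gang_free_point, solve_endemic
from .thresholds import gang_reproduction_number

__all__ = [
    "ScenarioResult",
    "IntegrationError",
    "integrate",
    "default_initial_state",
    "parameter_sweep",
    "rg_contour",
    "bifurcation_diagram",
    "hysteresis_probe",
]

logger = logging.getLogger(__name__)

DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-10
DEFAULT_N_OUT = 1001


class IntegrationError(RuntimeError):
    """Integrator failure, carrying the time at which it occurred."""

    def __init__(self, message: str, t_fail: float):
        super().__init__(f"{message} (t = {t_fail:g})")
        self.t_fail = t_fail


def integrate(
    params: Parameters,
    init: State,
    t_end: float,
    n_out: int = DEFAULT_N_OUT,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> Trajectory:
    """Solve the system from ``init`` to ``t_end`` on a uniform output grid."""
    q = require_valid(params)
    init.require_nonnegative()
    if t_end <= 0:
        raise ValueError(f"t_end must be positive, got {t_end}")
    if n_out < 2:
        raise ValueError(f"n_out must be at least 2, got {n_out}")
    times = np.linspace(0.0, t_end, n_out)
    sol = solve_ivp(
        lambda t, y: rhs_array(y, q),
        (0.0, t_end),
        init.as_array(),
        method="DOP853",
        t_eval=times,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise IntegrationError(sol.message, float(sol.t[-1]) if len(sol.t) else 0.0)
    states = sol.y.T.copy()
    # accumulated undershoot at an absorbing zero scales with rtol * ||y||,
    # not with the per-step atol, so the clamping window uses both
    clamp_tol = max(atol, rtol * max(1.0, float(init.N), q.Lambda / q.mu))
    undershoot = states.min()
    if undershoot < -clamp_tol:
        idx = np.unravel_index(np.argmin(states), states.shape)
        raise IntegrationError(
            f"negative compartment {states[idx]:.3e} beyond the clamping window", float(times[idx[0]])
        )
    if undershoot < 0:
        logger.warning("clamping %d small negative value(s) (min %.3e) to zero", int((states < 0).sum()), undershoot)
        states[states < 0] = 0.0
    return Trajectory(times=times, states=states)


def default_initial_state(params: Parameters, g_frac: float = 0.01) -> State:
    """Gang-free equilibrium seeded with a small gang nucleus.

    G(0) = g_frac * Lambda/mu (default 1% of the asymptotic population),
    C(0) = 0.  This is the documented starting point for scenario runs.
    """
    q = require_valid(params)
    gfe = gang_free_point(q, assess=False).state
    return State(Sn=gfe.Sn, Sr=gfe.Sr, G=g_frac * q.Lambda / q.mu, C=0.0)


@dataclass(frozen=True)
class ScenarioResult:
    """Horizon summary of a one-parameter sweep.

    ``pct_change[i]`` is the relative reduction from value i to value
    i+1, i.e. 100 * (G_i - G_{i+1}) / G_i at the horizon.
    """

    parameter: str
    values: np.ndarray
    g_at_horizon: np.ndarray
    pct_change: np.ndarray
    t_end: float

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "value": self.values,
                "G_at_horizon": self.g_at_horizon,
                "pct_change": np.concatenate([[np.nan], self.pct_change]),
            }
        )


def parameter_sweep(
    params: Parameters,
    name: str,
    values,
    init: State | None = None,
    t_end: float = 100.0,
    n_out: int = DEFAULT_N_OUT,
) -> ScenarioResult:
    """Integrate once per swept value and record G at the horizon."""
    q = require_valid(params)
    values = np.asarray(list(values), dtype=float)
    if len(values) == 0:
        raise ValueError("sweep needs at least one value")
    if np.any(np.diff(values) <= 0):
        raise ValueError("sweep values must be strictly increasing")
    if init is None:
        init = default_initial_state(q)
    g_final = []
    for value in values:
        trial = q.replace(**{name: float(value)})
        from .model import validate as _validate

        violations = _validate(trial)
        if violations:
            raise ValueError(f"swept value {name}={value} is invalid: {violations}")
        traj = integrate(trial, init, t_end=t_end, n_out=n_out)
        g_final.append(traj.G[-1])
    g_final = np.asarray(g_final)
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = 100.0 * (g_final[:-1] - g_final[1:]) / g_final[:-1]
    return ScenarioResult(parameter=name, values=values, g_at_horizon=g_final, pct_change=pct, t_end=t_end)


def rg_contour(params: Parameters, sigma2_values, gamma_values) -> np.ndarray:
    """Rg on a (gamma x sigma2) grid: rows indexed by gamma, columns by sigma2."""
    q = require_valid(params)
    sigma2_values = np.asarray(list(sigma2_values), dtype=float)
    gamma_values = np.asarray(list(gamma_values), dtype=float)
    grid = np.empty((len(gamma_values), len(sigma2_values)))
    for i, g in enumerate(gamma_values):
        for j, s2 in enumerate(sigma2_values):
            grid[i, j] = gang_reproduction_number(q.replace(gamma=float(g), sigma2=float(s2)))
    return grid


def contour_frame(params: Parameters, sigma2_values, gamma_values):
    """Long-format (sigma2, gamma, Rg) DataFrame for the contour grid."""
    import pandas as pd

    sigma2_values = np.asarray(list(sigma2_values), dtype=float)
    gamma_values = np.asarray(list(gamma_values), dtype=float)
    grid = rg_contour(params, sigma2_values, gamma_values)
    rows = [
        {"sigma2": s2, "gamma": g, "Rg": grid[i, j]}
        for i, g in enumerate(gamma_values)
        for j, s2 in enumerate(sigma2_values)
    ]
    return pd.DataFrame(rows)


def bifurcation_diagram(params: Parameters, beta_range: tuple[float, float], n_points: int = 101):
    """Equilibrium branches G*(Rg) as beta sweeps over ``beta_range``.

    Returns a DataFrame with columns (beta, Rg, G_star, stability,
    branch); the gang-free branch G* = 0 is always included with its
    own stability label, endemic branches appear per admissible root.
    """
    import pandas as pd

    q = require_valid(params)
    lo, hi = beta_range
    if not (0 < lo < hi):
        raise ValueError(f"beta range must satisfy 0 < lo < hi, got {beta_range}")
    rows = []
    for beta in np.linspace(lo, hi, n_points):
        trial = q.replace(beta=float(beta))
        rg = gang_reproduction_number(trial)
        gfe = gang_free_point(trial)
        rows.append(
            {"beta": beta, "Rg": rg, "G_star": 0.0, "stability": gfe.stability, "branch": "gang_free"}
        )
        for pt in (assess_stability(trial, p) for p in solve_endemic(trial)):
            rows.append(
                {
                    "beta": beta,
                    "Rg": rg,
                    "G_star": pt.state.G,
                    "stability": pt.stability,
                    "branch": "endemic",
                }
            )
    return pd.DataFrame(rows)


def hysteresis_probe(
    params: Parameters,
    g0_small: float,
    g0_large: float,
    t_end: float,
    n_out: int = DEFAULT_N_OUT,
) -> tuple[State, State]:
    """Terminal states of two runs differing only in the initial gang size.

    In the bistable (backward-bifurcation) window the small seed decays
    to the gang-free state while the large seed is captured by the upper
    endemic branch.
    """
    q = require_valid(params)
    base = gang_free_point(q, assess=False).state
    finals = []
    for g0 in (g0_small, g0_large):
        init = State(Sn=base.Sn, Sr=base.Sr, G=float(g0), C=0.0)
        finals.append(integrate(q, init, t_end=t_end, n_out=n_out).final_state())
    return finals[0], finals[1]
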