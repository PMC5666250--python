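"""Named parameter fixtures used throughout the package and its tests.

Three fixtures are shipped:

* ``table1`` — the baseline rate estimates (gamma, theta, beta, eta,
  sigma1, sigma2).  The source table prints no values for Lambda, mu,
  p, nu or epsilon; this package supplies documented defaults for them,
  flagged as repo-supplied assumptions.
* ``bifurcation_fig2`` — the complete parameter set of the backward-
  bifurcation example (all eleven values cited).
* ``demographics`` — ``table1`` with the demographic pair mu = 0.0166
  per year (60-year life expectancy) and Lambda = 0.028 (South African
  birth rate), both cited.
"""

from __future__ import annotations

from dataclasses import dataclass

from .model import PARAMETER_NAMES, Parameters, require_valid

__all__ = ["FixtureSet", "FIXTURE_NAMES", "load_fixture"]

FIXTURE_NAMES = ("table1", "bifurcation_fig2", "demographics")

# Proportions p, nu, epsilon are printed only as ranges (0, 1); the
# repo-supplied default for each is the midpoint 0.5.
_DEFAULT_PROPORTIONS = {"p": 0.5, "nu": 0.5, "epsilon": 0.5}


@dataclass(frozen=True)
class FixtureSet:
    """A named parameter set with per-field provenance.

    ``provenance`` maps every field to a short citation note;
    ``defaults`` lists the fields whose values are repo-supplied
    assumptions rather than printed estimates.
    """

    name: str
    params: Parameters
    provenance: dict[str, str]
    defaults: frozenset[str]


def _table1() -> FixtureSet:
    cited = {
        "gamma": "baseline table: sentencing rate 0.8",
        "theta": "baseline table: transition rate Sn->Sr 0.3",
        "beta": "baseline table: effective contact rate 0.01",
        "eta": "baseline table: imitation coefficient 0.002",
        "sigma1": "baseline table: release rate 0.5",
        "sigma2": "baseline table: natural recovery rate 0.5",
    }
    defaults = {
        "Lambda": "repo default 0.028 (demographic recruitment; not in the baseline table)",
        "mu": "repo default 0.0166/year (60-year life expectancy; not in the baseline table)",
        "p": "repo default 0.5 (printed only as a (0,1) range)",
        "nu": "repo default 0.5 (printed only as a (0,1) range)",
        "epsilon": "repo default 0.5 (printed only as a (0,1) range)",
    }
    params = Parameters(
        Lambda=0.028,
        mu=0.0166,
        p=0.5,
        theta=0.3,
        beta=0.01,
        eta=0.002,
        sigma1=0.5,
        sigma2=0.5,
        gamma=0.8,
        epsilon=0.5,
        nu=0.5,
    )
    return FixtureSet("table1", params, {**cited, **defaults}, frozenset(defaults))


def _bifurcation_fig2() -> FixtureSet:
    params = Parameters(
        Lambda=0.047,
        mu=0.02,
        p=0.4,
        theta=0.13,
        beta=0.3,
        eta=10.0,
        sigma1=0.1,
        sigma2=0.5,
        gamma=0.5,
        epsilon=0.5,
        nu=0.7,
    )
    provenance = {name: "backward-bifurcation example set (all values cited)" for name in PARAMETER_NAMES}
    return FixtureSet("bifurcation_fig2", params, provenance, frozenset())


def _demographics() -> FixtureSet:
    base = _table1()
    provenance = dict(base.provenance)
    provenance["mu"] = "demographics: 60-year life expectancy => mu = 0.0166 per year"
    provenance["Lambda"] = "demographics: birth rate => Lambda = 0.028"
    defaults = base.defaults - {"mu", "Lambda"}
    return FixtureSet("demographics", base.params.replace(mu=0.0166, Lambda=0.028), provenance, defaults)


_BUILDERS = {
    "table1": _table1,
    "bifurcation_fig2": _bifurcation_fig2,
    "demographics": _demographics,
}


def load_fixture(name: str) -> FixtureSet:
    """Return a named fixture; unknown names list the available ones."""
    try:
        builder = _BUILDERS[name]
    except KeyError:
        raise KeyError(f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}") from None
    fixture = builder()
    require_valid(fixture.params)
    return fixture
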