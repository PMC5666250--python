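import numpy as np
import pytest

from gangdyn import Parameters, load_fixture, validate

#: Seed for every numpy-based property test in the suite.
SUITE_SEED = 20170511


@pytest.fixture(scope="session")
def fig2() -> Parameters:
    """The backward-bifurcation example parameter set."""
    return load_fixture("bifurcation_fig2").params


@pytest.fixture(scope="session")
def table1() -> Parameters:
    """Baseline rate estimates with the repo-supplied proportion defaults."""
    return load_fixture("table1").params


def sample_parameters(rng: np.random.Generator) -> Parameters:
    """One random valid parameter set: rates log-uniform on [1e-3, 2],
    proportions uniform on [0, 1]."""

    def rate() -> float:
        return float(np.exp(rng.uniform(np.log(1e-3), np.log(2.0))))

    params = Parameters(
        Lambda=rate(),
        mu=rate(),
        p=float(rng.uniform()),
        theta=rate(),
        beta=rate(),
        eta=rate(),
        sigma1=rate(),
        sigma2=rate(),
        gamma=rate(),
        epsilon=float(rng.uniform()),
        nu=float(rng.uniform()),
    )
    assert not validate(params)
    return params


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(SUITE_SEED)
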