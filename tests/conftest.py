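import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import sizebef as sb

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params() -> sb.AllometricParams:
    """The shipped default physiology."""
    return sb.AllometricParams()


@pytest.fixture(scope="session")
def eco() -> sb.EcosystemParams:
    """The shipped default ecosystem parameters."""
    return sb.EcosystemParams()


@pytest.fixture(scope="session")
def env_mid(params) -> sb.Environment:
    """A mid-range environment: neither replete nor starved."""
    return sb.Environment(N=1.0, fer=0.6, I=100.0)


@pytest.fixture(scope="session")
def env_replete() -> sb.Environment:
    """Effectively unlimited resources."""
    return sb.Environment(N=1.0e9, fer=1.0e9, I=1.0e9)


def gauss_hermite_expectation(f, mean, var, n_nodes=64):
    """E[f(L)] for L ~ Normal(mean, var) by Gauss-Hermite quadrature."""
    x, w = np.polynomial.hermite.hermgauss(n_nodes)
    nodes = mean + np.sqrt(2.0 * var) * x
    return float(np.sum(w * f(nodes)) / np.sqrt(np.pi))


@pytest.fixture(scope="session")
def gh_expectation():
    return gauss_hermite_expectation
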