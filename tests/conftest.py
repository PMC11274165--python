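import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from vedolink import PDParameters, PKParameters, fixture_cohort

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def pk():
    """Reference kinetic constants of the two-compartment blood model."""
    return PKParameters(qb=0.12, v1=3.12, v2=1.65, k=0.0368)


@pytest.fixture(scope="session")
def pdp():
    """Reference Hill-effect constants for MAdCAM-1 suppression."""
    return PDParameters(m0=2.23e-2, emax=0.956, gamma=0.3512, e50=0.093)


@pytest.fixture(scope="session")
def cohort():
    """The 11 in-study patients with score and RHI triplets."""
    return fixture_cohort()


def rk4_two_compartment(pk, c1_0, t_end, h=1e-4):
    """Brute-force fixed-step RK4 integration of the linear system.

    Independent oracle: never calls the package's solvers.
    """
    a = pk.qb / pk.v1
    b = pk.qb / pk.v2

    def f(x):
        return np.array([a * (x[1] - x[0]), b * (x[0] - x[1]) - pk.k * x[1]])

    n = int(round(t_end / h))
    x = np.array([float(c1_0), 0.0])
    for _ in range(n):
        k1 = f(x)
        k2 = f(x + 0.5 * h * k1)
        k3 = f(x + 0.5 * h * k2)
        k4 = f(x + h * k3)
        x = x + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
    return x[0], x[1]
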