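import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from vitcclock import DimensionlessGroups

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def reference_groups():
    """The reference parameter point (rho, eps, phi) = (2, 1e-3, 0.2)."""
    return DimensionlessGroups(rho=2.0, eps=1e-3, phi=0.2)


def rk4_integrate(f, y0, t_end, h):
    """Fixed-step classical Runge-Kutta reference integrator.

    Deliberately independent of scipy's machinery: a plain loop over RK4
    stages, used as the oracle against which the stiff solver is checked.
    Returns (times, states) sampled at every step.
    """
    n = int(round(t_end / h))
    ts = np.empty(n + 1)
    ys = np.empty((n + 1, len(y0)))
    y = np.array(y0, dtype=float)
    ts[0], ys[0] = 0.0, y
    for i in range(n):
        k1 = f(y)
        k2 = f(y + 0.5 * h * k1)
        k3 = f(y + 0.5 * h * k2)
        k4 = f(y + h * k3)
        y = y + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        ts[i + 1] = (i + 1) * h
        ys[i + 1] = y
    return ts, ys


@pytest.fixture(scope="session")
def rk4():
    return rk4_integrate
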