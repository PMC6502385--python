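"""Mass-action ODE model of the vitamin C iodine clock reaction.

The chemistry is reduced to two reactions: a slow production of the clock
chemical iodine from iodide, ``2A -> B`` at rate ``k0*a**2``, and a fast
inhibition ``B + C -> 2A`` at rate ``k1*b*c`` in which ascorbic acid (the
inhibitor C) converts iodine back to iodide.  Hydrogen peroxide is held in
great excess and does not appear as a dynamic species.  The total iodine
atom concentration ``a + 2b`` is conserved, which reduces the model to two
variables; in dimensionless form

    dbeta/dtau  = -beta*gamma + eps*rho*(1 - 2*beta)**2
    dgamma/dtau = -rho*beta*gamma

with ``beta = b/m0``, ``gamma = c/c0``, ``tau = k1*c0*t`` and the groups
``rho = m0/c0``, ``eps = k0/k1``, ``phi = b0/m0``.  During the induction
period the fast reaction holds beta at O(eps); once the inhibitor is
exhausted beta rises rapidly to its equilibrium value 1/2 — the visible
"switchover" of the clock.

This module owns the dimensional and dimensionless right-hand sides, the
nondimensionalization round trip, stiff numerical integration of the
reduced system, numerical switchover detection on the dense solver output,
the closed-form equilibrium analysis and the quasi-steady induction curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .exceptions import (
    ClockValidationError,
    InvalidStateError,
    SolverError,
    SwitchoverNotReachedError,
)

__all__ = [
    "KineticParameters",
    "DimensionlessGroups",
    "Trajectory",
    "EquilibriumReport",
    "rhs_dimensional",
    "rhs_dimensionless",
    "nondimensionalize",
    "dimensionalize",
    "simulate",
    "corner_threshold",
    "detect_switchover",
    "equilibrium_analysis",
    "quasi_steady_curve",
]

#: Default stiff-solver tolerances.  gamma must be resolved down to
#: O(sqrt(eps)) in the corner region, hence the tight absolute tolerance.
DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-12

def corner_threshold(eps: float) -> float:
    """Default switchover-detection level sqrt(2*eps/pi).

    This is the leading-order value of beta at the centre of the corner
    layer, so the up-crossing of beta through it lands on the asymptotic
    switchover time to within the O(eps**-1/2) corner width.  A fixed
    O(1) level (say 1/4) would instead be crossed much later, during the
    slow algebraic relaxation towards the equilibrium value 1/2.
    """
    return float(np.sqrt(2.0 * eps / np.pi))


@dataclass(frozen=True)
class KineticParameters:
    """Dimensional rate constants and initial concentrations.

    Parameters
    ----------
    k0 : float
        Slow-reaction rate constant (iodide -> iodine), M^-1 s^-1.
    k1 : float
        Fast-reaction rate constant (iodine + ascorbic acid), M^-1 s^-1.
    a0, b0, c0 : float
        Initial iodide, iodine and ascorbic-acid concentrations, mol l^-1.
    """

    k0: float
    k1: float
    a0: float
    b0: float
    c0: float

    def __post_init__(self) -> None:
        for name in ("k0", "k1", "a0", "b0", "c0"):
            if getattr(self, name) < 0:
                raise ClockValidationError(f"{name} must be >= 0, got {getattr(self, name)!r}")
        if self.k1 <= 0:
            raise ClockValidationError("k1 must be > 0")
        if self.c0 <= 0:
            raise ClockValidationError("c0 must be > 0")
        if self.m0 <= 0:
            raise ClockValidationError("m0 = a0 + 2*b0 must be > 0")

    @property
    def m0(self) -> float:
        """Total iodine-atom concentration a0 + 2*b0, mol l^-1 (conserved)."""
        return self.a0 + 2.0 * self.b0


@dataclass(frozen=True)
class DimensionlessGroups:
    """The three dimensionless groups plus the scalings back to dimensions.

    ``rho = m0/c0`` (reactant ratio), ``eps = k0/k1`` (slow/fast rate
    ratio, small), ``phi = b0/m0`` (initial iodine fraction).  The scale
    fields are NaN when the groups were constructed directly rather than
    from dimensional parameters.
    """

    rho: float
    eps: float
    phi: float
    time_scale: float = float("nan")  # (k1*c0)^-1, seconds
    conc_scale_b: float = float("nan")  # m0, mol l^-1
    conc_scale_c: float = float("nan")  # c0, mol l^-1

    def __post_init__(self) -> None:
        if not self.rho > 0:
            raise ClockValidationError(f"rho must be > 0, got {self.rho!r}")
        if not self.eps >= 0:
            raise ClockValidationError(f"eps must be >= 0, got {self.eps!r}")
        if not 0.0 <= self.phi <= 0.5:
            raise ClockValidationError(f"phi must lie in [0, 1/2], got {self.phi!r}")
        # The asymptotic machinery additionally needs 0 < eps << 1 and
        # rho*phi < 1; the ODEs themselves remain valid (eps = 0 simply
        # switches the slow reaction off), so only warn.
        if self.eps >= 0.1:
            warnings.warn(
                f"eps = {self.eps:g} is not small; asymptotic formulas are unreliable",
                stacklevel=2,
            )
        if self.rho * self.phi >= 1.0:
            warnings.warn(
                f"rho*phi = {self.rho * self.phi:g} >= 1: outside the asymptotic "
                "regime (inhibitor is exhausted during the initial transient)",
                stacklevel=2,
            )

    @property
    def has_scales(self) -> bool:
        return np.isfinite(self.time_scale)


@dataclass
class Trajectory:
    """Sampled solution of the reduced two-variable system.

    ``tau`` is strictly increasing; ``beta``/``gamma`` are the clock
    chemical and inhibitor samples.  ``dimensionless`` flags the unit
    convention (dimensionless (beta, gamma, tau) versus (b, c, t) in
    mol l^-1 and seconds).  ``meta`` records solver name, tolerances and
    the success flag.  A dense interpolant is kept (when available) for
    event location by :func:`detect_switchover`.
    """

    tau: np.ndarray
    beta: np.ndarray
    gamma: np.ndarray
    dimensionless: bool = True
    meta: dict = field(default_factory=dict)
    dense: object | None = None  # scipy OdeSolution, if the solver produced one

    def __post_init__(self) -> None:
        self.tau = np.asarray(self.tau, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        self.gamma = np.asarray(self.gamma, dtype=float)
        if not (self.tau.shape == self.beta.shape == self.gamma.shape):
            raise ClockValidationError("tau, beta, gamma must have matching shapes")
        if self.tau.size >= 2 and not np.all(np.diff(self.tau) > 0):
            raise ClockValidationError("tau samples must be strictly increasing")

    def to_dataframe(self):
        import pandas as pd

        if self.dimensionless:
            return pd.DataFrame({"tau": self.tau, "beta": self.beta, "gamma": self.gamma})
        return pd.DataFrame({"t_seconds": self.tau, "b": self.beta, "c": self.gamma})


@dataclass(frozen=True)
class EquilibriumReport:
    """Closed-form linearization at the unique equilibrium (1/2, 0)."""

    state: tuple[float, float]
    eigenvalues: tuple[float, float]
    eigenvectors: tuple[tuple[float, float], tuple[float, float]]
    manifold_labels: tuple[str, str]


def _check_nonnegative(state: Sequence[float], tol: float) -> np.ndarray:
    s = np.asarray(state, dtype=float)
    if np.any(s < -tol):
        raise InvalidStateError(f"negative concentration beyond tolerance {tol:g}: {s!r}")
    return np.clip(s, 0.0, None)


def rhs_dimensional(
    state: Sequence[float], params: KineticParameters, *, tol: float = 1e-12
) -> tuple[float, float, float]:
    """Mass-action rates (da/dt, db/dt, dc/dt) for concentrations (a, b, c).

    Components within ``tol`` below zero are clipped to zero; anything more
    negative raises :class:`InvalidStateError`.  The returned rates satisfy
    da/dt + 2*db/dt = 0 identically (iodine-atom conservation).
    """
    a, b, c = _check_nonnegative(state, tol)
    slow = params.k0 * a * a  # 2A -> B
    fast = params.k1 * b * c  # B + C -> 2A
    return (2.0 * fast - 2.0 * slow, -fast + slow, -fast)


def rhs_dimensionless(
    state: Sequence[float], groups: DimensionlessGroups
) -> tuple[float, float]:
    """(dbeta/dtau, dgamma/dtau) of the reduced dimensionless system."""
    beta, gamma = state
    dbeta = -beta * gamma + groups.eps * groups.rho * (1.0 - 2.0 * beta) ** 2
    dgamma = -groups.rho * beta * gamma
    return (dbeta, dgamma)


def nondimensionalize(params: KineticParameters) -> DimensionlessGroups:
    """Form (rho, eps, phi) and the scalings from dimensional parameters."""
    if params.c0 == 0:
        raise ClockValidationError("cannot nondimensionalize: c0 is zero")
    if params.k1 == 0:
        raise ClockValidationError("cannot nondimensionalize: k1 is zero")
    m0 = params.m0
    with warnings.catch_warnings():
        # regime warnings belong to the asymptotics, not to bookkeeping
        warnings.simplefilter("ignore")
        groups = DimensionlessGroups(
            rho=m0 / params.c0,
            eps=params.k0 / params.k1,
            phi=params.b0 / m0,
            time_scale=1.0 / (params.k1 * params.c0),
            conc_scale_b=m0,
            conc_scale_c=params.c0,
        )
    return groups


def dimensionalize(groups: DimensionlessGroups) -> KineticParameters:
    """Invert :func:`nondimensionalize` (requires the scale fields)."""
    if not groups.has_scales:
        raise ClockValidationError(
            "groups carry no dimensional scales; construct them via nondimensionalize()"
        )
    m0 = groups.conc_scale_b
    c0 = groups.conc_scale_c
    k1 = 1.0 / (groups.time_scale * c0)
    b0 = groups.phi * m0
    return KineticParameters(k0=groups.eps * k1, k1=k1, a0=m0 - 2.0 * b0, b0=b0, c0=c0)


def simulate(
    groups: DimensionlessGroups,
    tau_span: tuple[float, float],
    initial: tuple[float, float] | None = None,
    *,
    n_points: int = 2001,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    method: str = "LSODA",
) -> Trajectory:
    """Integrate the reduced dimensionless system with a stiff solver.

    The two-variable system is integrated directly, so the dimensional
    conservation law a + 2b = m0 holds exactly by construction (a is
    reconstructed as m0*(1 - 2*beta) when needed).  The default initial
    state is (phi, 1).

    Returns a :class:`Trajectory` sampled on ``n_points`` uniform times,
    with the solver's dense interpolant attached for event location.
    """
    t0, t1 = float(tau_span[0]), float(tau_span[1])
    if not (np.isfinite(t0) and np.isfinite(t1) and t1 > t0):
        raise ClockValidationError(f"tau_span must be finite and increasing, got {tau_span!r}")
    y0 = (groups.phi, 1.0) if initial is None else (float(initial[0]), float(initial[1]))

    sol = solve_ivp(
        lambda _t, y: rhs_dimensionless(y, groups),
        (t0, t1),
        y0,
        method=method,
        dense_output=True,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise SolverError(f"{method} failed: {sol.message}")

    tau = np.linspace(t0, t1, n_points)
    beta, gamma = sol.sol(tau)
    # clip solver-tolerance undershoots; anything worse is a real defect
    guard = 10.0 * atol
    if np.any(beta < -guard) or np.any(gamma < -guard):
        raise SolverError("negative concentrations beyond solver tolerance in trajectory")
    beta = np.clip(beta, 0.0, None)
    gamma = np.clip(gamma, 0.0, None)
    return Trajectory(
        tau=tau,
        beta=beta,
        gamma=gamma,
        dimensionless=True,
        meta={
            "solver": method,
            "rtol": rtol,
            "atol": atol,
            "success": True,
            "y0": y0,
            "rho": groups.rho,
            "eps": groups.eps,
            "phi": groups.phi,
        },
        dense=sol.sol,
    )


def detect_switchover(traj: Trajectory, threshold: float | None = None) -> float:
    """First up-crossing time of beta through ``threshold``.

    ``threshold`` defaults to the corner-layer level
    :func:`corner_threshold` ``= sqrt(2*eps/pi)`` (using the eps recorded
    in the trajectory metadata), which pins the detection to the rapid
    switchover itself rather than the slow later approach to equilibrium.
    Any initial transient in which beta starts above the threshold and
    decays is excluded: the search starts at the sampled minimum of beta.
    With a dense interpolant the crossing is refined by root-finding to
    relative 1e-8; otherwise it is located by linear interpolation between
    samples (adequate for noisy, smoothed data).

    Raises :class:`SwitchoverNotReachedError` if beta never crosses the
    threshold inside the trajectory window.
    """
    if threshold is None:
        eps = traj.meta.get("eps")
        if eps is None:
            raise ClockValidationError(
                "trajectory metadata lacks 'eps'; pass an explicit threshold"
            )
        threshold = corner_threshold(eps)
    beta = traj.beta
    start = int(np.argmin(beta))
    above = beta[start:] > threshold
    if not np.any(above):
        raise SwitchoverNotReachedError(
            f"beta never exceeds {threshold:g} after its minimum; "
            "extend the simulation window"
        )
    k = start + int(np.argmax(above))  # first sample strictly above threshold
    if k == 0:
        return float(traj.tau[0])
    lo, hi = traj.tau[k - 1], traj.tau[k]
    if traj.dense is not None:
        f = lambda t: traj.dense(t)[0] - threshold
        if f(lo) > 0:  # threshold crossed within the very first interval
            return float(lo)
        return float(brentq(f, lo, hi, xtol=1e-300, rtol=1e-10))
    # fall back to linear interpolation on the samples
    b0, b1 = beta[k - 1], beta[k]
    return float(lo + (threshold - b0) / (b1 - b0) * (hi - lo))


def equilibrium_analysis(groups: DimensionlessGroups) -> EquilibriumReport:
    """Closed-form linearization at the unique equilibrium (1/2, 0).

    The Jacobian there has eigenvalue 0 with eigenvector (1, 0) — the slow
    manifold gamma = 0 along which the system creeps after switchover —
    and eigenvalue -rho/2 with eigenvector (1, rho), a stable manifold
    lying outside the physical region.  No numeric linear algebra is used.
    """
    return EquilibriumReport(
        state=(0.5, 0.0),
        eigenvalues=(0.0, -groups.rho / 2.0),
        eigenvectors=((1.0, 0.0), (1.0, groups.rho)),
        manifold_labels=("slow", "stable"),
    )


def quasi_steady_curve(
    beta_grid: Sequence[float], groups: DimensionlessGroups
) -> np.ndarray:
    """Induction-phase quasi-steady manifold gamma = eps*rho*(1-2*beta)**2/beta.

    Evaluated pointwise on ``beta_grid`` (values in (0, 1/2]); beta = 0
    yields ``inf`` rather than an exception.
    """
    beta = np.asarray(beta_grid, dtype=float)
    if np.any(beta < 0) or np.any(beta > 0.5):
        raise ClockValidationError("beta_grid values must lie in [0, 1/2]")
    with np.errstate(divide="ignore"):
        return groups.eps * groups.rho * (1.0 - 2.0 * beta) ** 2 / beta
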