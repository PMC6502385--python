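"""Matched-asymptotic solutions of the clock-reaction system for eps << 1.

Four time regions are glued together by matching:

* **Region I** (initial adjustment, tau = O(1)): the slow reaction is
  negligible and the leading-order flow conserves rho*beta - gamma, giving
  a logistic-type closed form that relaxes to (0, 1 - rho*phi).
* **Region II** (induction, tau = O(1/eps)): quasi-steady balance
  beta*gamma = eps*rho with gamma draining linearly at rate rho**2*eps.
  The solution blows up as tau -> (1 - rho*phi)/(rho**2*eps) — the
  switchover time.
* **Region III** (corner, width O(eps**-1/2) around the switchover): both
  variables are O(sqrt(eps)); the layer equation is a Riccati equation
  whose solution is a Gaussian over an error function.
* **Region IV** (long term): gamma is zero beyond all algebraic orders and
  beta relaxes algebraically to the equilibrium value 1/2.

The matching constants are c1 = 1 - rho*phi (I<->II), c2 = 1 + 2*phi -
2/rho (III<->IV), c3 = 0 and c4 = 1 (II<->III).

A note on the region-III closed form: the layer variables obey
d(gamma_bar)/d(tau_bar) = -(rho**2*tau_bar + gamma_bar)*gamma_bar, solved
by gamma_bar = u'/u with u' = exp(-rho**2*tau_bar**2/2).  Both beta and
gamma therefore carry the *same* Gaussian factor
exp(-(rho*eps*tau - [1/rho - phi])**2 / (2*eps)), and the error-function
argument is that quantity over sqrt(2*eps).  The formulas here are
evaluated from this derivation, in a scaled complementary-error-function
form (erfcx) that is finite for arbitrarily large |tau_bar|.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.optimize import brentq
from scipy.special import erfcx

from .exceptions import (
    DegenerateParameterError,
    NoInductionError,
    NoSwitchoverError,
    OutOfValidityError,
)
from .model_core import DimensionlessGroups

__all__ = [
    "MatchingConstants",
    "RegionSolution",
    "region1",
    "region2",
    "region3",
    "region4",
    "region_boundaries",
    "composite_eval",
    "switchover_tau",
    "switchover_time_seconds",
]

REGIONS = ("I", "II", "III", "IV")


@dataclass(frozen=True)
class MatchingConstants:
    """Integration constants fixed by matching adjacent regions."""

    c1: float  # region II offset: gamma at the start of induction
    c2: float  # region IV constant
    c3: float  # corner-layer shift, zero by matching to region II
    c4: float  # corner-layer erf constant, one by decay as tau_bar -> -inf

    @classmethod
    def from_groups(cls, groups: DimensionlessGroups) -> "MatchingConstants":
        _require_nondegenerate(groups)
        return cls(
            c1=1.0 - groups.rho * groups.phi,
            c2=1.0 + 2.0 * groups.phi - 2.0 / groups.rho,
            c3=0.0,
            c4=1.0,
        )


@dataclass(frozen=True)
class RegionSolution:
    """One region's closed-form solution with its validity interval."""

    region_id: str
    validity: tuple[float, float]
    beta_fn: Callable[[np.ndarray], np.ndarray]
    gamma_fn: Callable[[np.ndarray], np.ndarray]
    order: str  # error-order tag, e.g. "O(eps)" or "beyond-algebraic"


def _require_nondegenerate(groups: DimensionlessGroups) -> None:
    if groups.rho * groups.phi == 1.0:
        raise DegenerateParameterError(
            "rho*phi = 1 is degenerate (the region-I denominator vanishes)"
        )


def region1(tau, groups: DimensionlessGroups):
    """Initial-adjustment solution, exact in the eps -> 0 limit.

    beta(0) = phi and gamma(0) = 1 exactly; as tau -> inf the pair tends
    to (0, 1 - rho*phi).
    """
    _require_nondegenerate(groups)
    tau = np.asarray(tau, dtype=float)
    rp = groups.rho * groups.phi
    e = np.exp((rp - 1.0) * tau)
    # grouped so that beta(0) = phi exactly in floating point
    beta = groups.phi * ((1.0 - rp) * e / (1.0 - rp * e))
    # rho*beta - gamma is conserved by the leading-order flow; grouped so
    # that gamma(0) = 1 exactly
    gamma = groups.rho * beta + (1.0 - rp)
    return beta, gamma


def region2(tau, groups: DimensionlessGroups):
    """Induction (quasi-steady) solution; valid for tau below the blow-up.

    Returns (eps*rho/g, g) with g = 1 - rho*phi - rho**2*eps*tau, so that
    beta*gamma = eps*rho holds exactly.
    """
    tau = np.asarray(tau, dtype=float)
    blow_up = switchover_tau(groups)
    if np.any(tau >= blow_up):
        raise OutOfValidityError(
            f"region II is valid only for tau < {blow_up:g} (quasi-steady blow-up)"
        )
    gamma = 1.0 - groups.rho * groups.phi - groups.rho**2 * groups.eps * tau
    beta = groups.eps * groups.rho / gamma
    return beta, gamma


def region3(tau, groups: DimensionlessGroups):
    """Corner-layer solution around the switchover, in erfcx form.

    With w = rho*eps*tau - (1/rho - phi) and x = w/sqrt(2*eps):

        gamma = sqrt(eps) * rho * sqrt(2/pi) / erfcx(-x)
        beta  = gamma/rho + w

    which is the Gaussian-over-(1+erf) closed form rewritten so that it
    neither overflows nor hits 0/0 for large |x|.  Globally evaluable;
    meaningful within O(eps**-1/2) of the switchover time.
    """
    _require_nondegenerate(groups)
    tau = np.asarray(tau, dtype=float)
    w = groups.rho * groups.eps * tau - (1.0 / groups.rho - groups.phi)
    x = w / np.sqrt(2.0 * groups.eps)
    with np.errstate(over="ignore"):
        denom = erfcx(-x)  # = exp(x**2)*(1 + erf(x)); overflows to inf -> gamma 0
        gamma = np.sqrt(groups.eps) * groups.rho * np.sqrt(2.0 / np.pi) / denom
    gamma = np.where(np.isfinite(gamma), gamma, 0.0)
    beta = gamma / groups.rho + w
    return beta, gamma


def region4(tau, groups: DimensionlessGroups):
    """Long-term solution: gamma = 0 beyond all algebraic orders.

    With gamma identically zero the clock chemical obeys
    dbeta/dtau = eps*rho*(1 - 2*beta)**2, whose solution through the
    matching condition beta -> 0 at the switchover time is

        beta = 1/2 - 1/(2*(1 + 2*[phi - 1/rho + rho*eps*tau]))

    (c2 = 1 + 2*phi - 2/rho), rising algebraically to the equilibrium
    value 1/2 as tau -> inf.
    """
    tau = np.asarray(tau, dtype=float)
    arg = 1.0 + 2.0 * (groups.phi - 1.0 / groups.rho + groups.rho * groups.eps * tau)
    if np.any(arg <= 0):
        raise OutOfValidityError(
            "region IV evaluated before its validity onset (denominator <= 0)"
        )
    beta = 0.5 - 1.0 / (2.0 * arg)
    return beta, np.zeros_like(beta)


def _region1_settling_time(groups: DimensionlessGroups, tol: float = 1e-6) -> float:
    """tau at which the region-I solution is within ``tol`` of its limit."""
    if groups.phi == 0.0:
        return 0.0
    limit = 1.0 - groups.rho * groups.phi

    def gap(tau: float) -> float:
        b, g = region1(tau, groups)
        return float(abs(b) + abs(g - limit)) - tol

    if gap(0.0) <= 0:
        return 0.0
    hi = 1.0
    while gap(hi) > 0 and hi < 1e8:
        hi *= 2.0
    return float(brentq(gap, 0.0, hi))


def region_boundaries(groups: DimensionlessGroups, settle_tol: float = 1e-6):
    """Transition times (tau_I, tau_II_III, tau_III_IV) used piecewise.

    Region I runs until its solution has settled to within ``settle_tol``
    of its long-time limit; region III occupies a band of half-width
    3*sqrt(eps)/rho in the slow time eps*tau around the switchover;
    region II sits between, region IV after.
    """
    tau_sw = switchover_tau(groups)
    half_width = 3.0 * np.sqrt(groups.eps) / (groups.rho * groups.eps)
    tau_i = _region1_settling_time(groups, settle_tol)
    tau_ii_iii = max(tau_i, tau_sw - half_width)
    tau_iii_iv = tau_sw + half_width
    return tau_i, tau_ii_iii, tau_iii_iv


def composite_eval(tau, groups: DimensionlessGroups):
    """Piecewise evaluation: pick the region for each tau and evaluate it.

    Returns (beta, gamma, region_id) arrays; region_id entries are the
    strings "I", "II", "III", "IV".  The pieces agree to O(sqrt(eps)) at
    the boundaries.  No additive uniform composite is formed — the
    presentation is deliberately piecewise.
    """
    _require_nondegenerate(groups)
    tau = np.atleast_1d(np.asarray(tau, dtype=float))
    tau_i, tau_ii_iii, tau_iii_iv = region_boundaries(groups)
    beta = np.empty_like(tau)
    gamma = np.empty_like(tau)
    region = np.empty(tau.shape, dtype="U3")

    masks = {
        "I": tau <= tau_i,
        "II": (tau > tau_i) & (tau < tau_ii_iii),
        "III": (tau >= tau_ii_iii) & (tau <= tau_iii_iv),
        "IV": tau > tau_iii_iv,
    }
    fns = {"I": region1, "II": region2, "III": region3, "IV": region4}
    for name, mask in masks.items():
        if np.any(mask):
            b, g = fns[name](tau[mask], groups)
            beta[mask], gamma[mask], region[mask] = b, g, name
    return beta, gamma, region


def switchover_tau(groups: DimensionlessGroups) -> float:
    """Dimensionless switchover time (1 - rho*phi)/(rho**2*eps).

    This is the blow-up time of the induction-phase solution; it requires
    rho*phi < 1, i.e. enough inhibitor to outlast the initial transient.
    """
    rp = groups.rho * groups.phi
    if rp >= 1.0:
        raise NoSwitchoverError(
            f"rho*phi = {rp:g} >= 1: the inhibitor is consumed in the initial "
            "transient and no induction period exists"
        )
    if groups.eps == 0.0:
        raise NoSwitchoverError("eps = 0: the slow reaction is off, no switchover")
    return (1.0 - rp) / (groups.rho**2 * groups.eps)


def switchover_time_seconds(c0: float, m0: float, phi: float, k0: float) -> float:
    """Dimensional switchover time t_sw = (c0 - phi*m0)/(m0**2 * k0), seconds.

    c0 and m0 are the initial ascorbic-acid and total iodine-atom
    concentrations in mol l^-1 and k0 the slow rate constant in M^-1 s^-1.
    Notably independent of the fast rate constant k1.
    """
    if m0 <= 0 or k0 <= 0:
        raise NoInductionError("m0 and k0 must be positive")
    if c0 <= phi * m0:
        raise NoInductionError(
            f"c0 = {c0:g} <= phi*m0 = {phi * m0:g}: no induction period"
        )
    return (c0 - phi * m0) / (m0**2 * k0)
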