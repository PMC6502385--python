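"""Synthetic experiments with the statistical structure of the bench data.

Two generators:

* :func:`generate_switchover_dataset` draws noisy switchover times on a
  design of (c0, m0) conditions.  Timing noise is multiplicative
  log-normal, ``t_obs = t_model * exp(sigma*Z - sigma**2/2)`` with
  ``sigma = noise_cv`` — mean-preserving, and with a spread that grows
  with the time itself, as the repeat pairs of the bench data do (times
  span roughly 20–500 s and larger times scatter more).  The default
  cv of 0.08 is the scale of the printed repeat-pair spread.
* :func:`generate_trajectory_dataset` subsamples a stiff simulation and
  adds Gaussian noise to (beta, gamma), emulating a quantitative
  trajectory measurement.

All randomness flows from a single ``numpy`` Generator seeded by the
design, so identical seeds give identical datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import NoInductionError
from .inference import SwitchoverDataset, SwitchoverRecord, load_table1_fixture, predict_tsw
from .model_core import DimensionlessGroups, Trajectory, simulate
from .wet_prep import Recipe, recipe_to_concentrations

__all__ = [
    "SyntheticDesign",
    "table1_conditions",
    "generate_switchover_dataset",
    "generate_trajectory_dataset",
]


@dataclass
class SyntheticDesign:
    """Design of a synthetic switchover-time experiment.

    ``conditions`` may mix (c0, m0) pairs and :class:`Recipe` objects
    (recipes are converted through the stoichiometry).  Defaults mirror
    the bench protocol: two repeats per condition, cv = 0.08.
    """

    conditions: list
    true_k0: float  # M^-1 s^-1
    true_phi: float = 0.0
    n_repeats: int = 2
    noise_cv: float = 0.08
    seed: int = 0
    _resolved: list = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if not self.conditions:
            raise ValueError("conditions must be non-empty")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        resolved = []
        for cond in self.conditions:
            if isinstance(cond, Recipe):
                c0, m0, _ = recipe_to_concentrations(cond)
            else:
                c0, m0 = float(cond[0]), float(cond[1])
            resolved.append((c0, m0))
        self._resolved = resolved


def table1_conditions() -> list[tuple[float, float]]:
    """The nine unique (c0, m0) conditions of the packaged benchmark grid."""
    ds = load_table1_fixture(deduplicate=True)
    seen: dict[tuple[float, float], None] = {}
    for r in ds.records:
        seen.setdefault((r.c0, r.m0))
    return list(seen)


def generate_switchover_dataset(design: SyntheticDesign) -> SwitchoverDataset:
    """Draw a noisy switchover-time dataset from a design.

    Each condition contributes ``n_repeats`` records with
    t_obs = predict_tsw * exp(sigma*Z - sigma**2/2), sigma = noise_cv.
    Conditions with c0 <= phi*m0 have no induction period and are
    rejected up front, naming the offender.
    """
    rng = np.random.default_rng(design.seed)
    records = []
    for i, (c0, m0) in enumerate(design._resolved):
        if c0 <= design.true_phi * m0:
            raise NoInductionError(
                f"condition {i} (c0={c0:g}, m0={m0:g}): c0 <= phi*m0, "
                "no induction period"
            )
        t_model = float(predict_tsw(c0, m0, design.true_k0, design.true_phi))
        sigma = design.noise_cv
        z = rng.standard_normal(design.n_repeats)
        t_obs = t_model * np.exp(sigma * z - sigma**2 / 2.0)
        for j, t in enumerate(t_obs, start=1):
            records.append(
                SwitchoverRecord(
                    condition_id=f"synth{i}",
                    c0=c0,
                    m0=m0,
                    t_obs=float(t),
                    series=f"rep{j}",
                )
            )
    return SwitchoverDataset(records=records)


def generate_trajectory_dataset(
    groups: DimensionlessGroups,
    noise_sd: float,
    n_points: int,
    seed: int,
    tau_span: tuple[float, float] = (0.0, 300.0),
) -> Trajectory:
    """Noisy subsample of a simulated trajectory (additive Gaussian noise).

    ``noise_sd = 0`` returns the exact subsample at ``n_points`` uniform
    times.  The returned trajectory carries no dense interpolant, so
    downstream event detection works on the samples alone — as it would
    on measured data.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    traj = simulate(groups, tau_span)
    rng = np.random.default_rng(seed)
    tau = np.linspace(tau_span[0], tau_span[1], n_points)
    beta = traj.dense(tau)[0] + noise_sd * rng.standard_normal(n_points)
    gamma = traj.dense(tau)[1] + noise_sd * rng.standard_normal(n_points)
    return Trajectory(
        tau=tau,
        beta=beta,
        gamma=gamma,
        dimensionless=True,
        meta={
            "noise_sd": noise_sd,
            "seed": seed,
            "source": "synthetic",
            "rho": groups.rho,
            "eps": groups.eps,
            "phi": groups.phi,
        },
        dense=None,
    )
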