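"""Least-squares estimation of (k0, phi) from switchover-time data.

The induction-period analysis yields a closed-form prediction for the
switchover time,

    t_sw = (c0 - phi*m0) / (m0**2 * k0),

which depends on the initial concentrations, the slow rate constant k0 and
the initial iodine fraction phi — but not on the fast rate constant k1.
Given a table of observed switchover times across conditions (c0, m0), the
two parameters are recovered by unconstrained least squares on residuals
in seconds.  The problem is near-linear in (1/k0, phi/k0), so a local
derivative-based solver converges readily; a coarse multistart guards the
result anyway.

The benchmark dataset — ten conditions spanning a grid of vitamin C and
Lugol's iodine amounts, two timed repeats each — ships with the package as
a plain CSV and loads via :func:`load_table1_fixture`.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .exceptions import (
    ClockValidationError,
    FixtureIntegrityError,
    IdentifiabilityError,
)

__all__ = [
    "SwitchoverRecord",
    "SwitchoverDataset",
    "FitResult",
    "predict_tsw",
    "fit",
    "load_table1_fixture",
]

_TABLE1_SHA256 = "17d4fff09e0ddf0fe8b3d6938f6328c6624ce584588fb54eece652f8faede61d"

#: Multistart grid guarding the local fit (crossed with the user's init).
_K0_STARTS = (0.1, 0.5, 1.0, 5.0)
_PHI_STARTS = (-0.1, 0.0, 0.1)


@dataclass(frozen=True)
class SwitchoverRecord:
    condition_id: str
    c0: float  # initial ascorbic acid, mol/l
    m0: float  # total iodine atoms, mol/l
    t_obs: float  # observed switchover time, seconds
    series: str = ""  # experimental series tag, e.g. "a" or "b"

    def __post_init__(self) -> None:
        if self.c0 <= 0 or self.m0 <= 0 or self.t_obs <= 0:
            raise ClockValidationError(
                f"record {self.condition_id!r}: c0, m0, t_obs must be > 0"
            )


@dataclass
class SwitchoverDataset:
    """Observed (c0, m0, t_sw) records; repeats are separate records."""

    records: list[SwitchoverRecord]

    def __post_init__(self) -> None:
        if len(self.records) < 3:
            raise ClockValidationError("need at least 3 records")
        if len(self.distinct_conditions()) < 2:
            raise IdentifiabilityError(
                "need at least 2 distinct (c0, m0) conditions to identify (k0, phi)"
            )

    def __len__(self) -> int:
        return len(self.records)

    def distinct_conditions(self) -> set[tuple[float, float]]:
        return {(r.c0, r.m0) for r in self.records}

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        c0 = np.array([r.c0 for r in self.records])
        m0 = np.array([r.m0 for r in self.records])
        t = np.array([r.t_obs for r in self.records])
        return c0, m0, t

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "condition_id": r.condition_id,
                    "c0": r.c0,
                    "m0": r.m0,
                    "t_obs": r.t_obs,
                    "series": r.series,
                }
                for r in self.records
            ]
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "SwitchoverDataset":
        return cls(
            records=[
                SwitchoverRecord(
                    condition_id=str(row["condition_id"]),
                    c0=float(row["c0"]),
                    m0=float(row["m0"]),
                    t_obs=float(row["t_obs"]),
                    series=str(row.get("series", "")),
                )
                for _, row in df.iterrows()
            ]
        )

    @classmethod
    def read_csv(cls, path) -> "SwitchoverDataset":
        return cls.from_dataframe(pd.read_csv(path))

    def write_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


@dataclass
class FitResult:
    """Fitted (k0, phi) with per-record residuals and diagnostics."""

    k0_hat: float  # M^-1 s^-1
    phi_hat: float  # dimensionless
    residuals: np.ndarray = field(repr=False)  # seconds, one per record
    rss: float = 0.0  # s^2
    converged: bool = True
    n_used: int = 0

    def to_dict(self) -> dict:
        return {
            "k0_hat": self.k0_hat,
            "phi_hat": self.phi_hat,
            "rss": self.rss,
            "converged": self.converged,
            "n_used": self.n_used,
            "residuals": [float(r) for r in self.residuals],
        }


def predict_tsw(c0, m0, k0: float, phi: float):
    """Model switchover time (c0 - phi*m0)/(m0**2 * k0), seconds.

    Vectorized over c0/m0.  May go negative for pathological phi — that is
    deliberate: the optimizer must be free to cross zero.
    """
    if k0 <= 0:
        raise ClockValidationError("k0 must be > 0")
    c0 = np.asarray(c0, dtype=float)
    m0 = np.asarray(m0, dtype=float)
    if np.any(m0 <= 0):
        raise ClockValidationError("m0 must be > 0")
    return (c0 - phi * m0) / (m0**2 * k0)


def fit(
    dataset: SwitchoverDataset,
    init: tuple[float, float] = (1.0, 0.1),
    *,
    multistart: bool = True,
) -> FitResult:
    """Unconstrained least squares of the switchover formula over (k0, phi).

    Minimizes sum((t_obs - predict_tsw)**2) with unweighted residuals in
    seconds, every repeat entering as its own record.  The objective is
    exactly linear in theta = (1/k0, phi/k0) — the model reads
    t = (c0/m0**2)*theta1 - (1/m0)*theta2 — so the global optimum is the
    ordinary linear least-squares solution, computed directly.  With
    ``multistart`` a derivative-based nonlinear solve is additionally run
    from ``init`` and a coarse (k0, phi) grid as an independent stability
    check; agreement (relative spread < 1e-6 among starts reaching the
    optimum) feeds the ``converged`` flag.  phi is unconstrained (a
    slightly negative estimate is a legitimate outcome of noise); a
    warning is emitted if it leaves the physical range [0, 1/2].
    """
    c0, m0, t_obs = dataset.arrays()

    def residual(p: np.ndarray) -> np.ndarray:
        k0, phi = p
        return t_obs - (c0 - phi * m0) / (m0**2 * k0)

    # exact optimum via the linear reparametrization
    A = np.column_stack([c0 / m0**2, -1.0 / m0])
    theta, *_ = np.linalg.lstsq(A, t_obs, rcond=None)
    if theta[0] <= 0:
        raise ClockValidationError(
            "least-squares optimum has non-positive k0; data inconsistent "
            "with the switchover model"
        )
    k0_hat = float(1.0 / theta[0])
    phi_hat = float(theta[1] / theta[0])

    converged = True
    if multistart:
        starts = [np.asarray(init, dtype=float)]
        starts += [np.array([k, p]) for k in _K0_STARTS for p in _PHI_STARTS]
        k0s = []
        best_rss = float(np.sum(residual(np.array([k0_hat, phi_hat])) ** 2))
        for x0 in starts:
            try:
                res = least_squares(residual, x0, method="lm", xtol=1e-14, ftol=1e-14)
            except Exception:
                continue
            if res.x[0] > 0 and 2.0 * res.cost <= best_rss * (1.0 + 1e-6) + 1e-12:
                k0s.append(res.x[0])
        spread = (max(k0s) - min(k0s)) / k0_hat if k0s else np.inf
        converged = bool(k0s and spread < 1e-6)
    if not 0.0 <= phi_hat <= 0.5:
        import warnings

        warnings.warn(
            f"fitted phi = {phi_hat:.3g} lies outside the physical range [0, 1/2]",
            stacklevel=2,
        )
    r = residual(np.array([k0_hat, phi_hat]))
    return FitResult(
        k0_hat=k0_hat,
        phi_hat=phi_hat,
        residuals=r,
        rss=float(np.dot(r, r)),
        converged=converged,
        n_used=len(dataset),
    )


def load_table1_fixture(deduplicate: bool = True) -> SwitchoverDataset:
    """Load the packaged benchmark dataset of observed switchover times.

    Ten printed conditions x two repeats = 20 records, tagged by series
    ("a": varying vitamin C at fixed iodine; "b": varying iodine at fixed
    vitamin C).  One physical condition is printed in both series with
    identical times; ``deduplicate=True`` (default) keeps only its first
    occurrence.  The file's checksum is verified on load.
    """
    ref = resources.files("vitcclock").joinpath("data/table1.csv")
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _TABLE1_SHA256:
        raise FixtureIntegrityError(
            f"packaged table1.csv checksum mismatch ({digest}); corrupted install?"
        )
    import io

    df = pd.read_csv(io.BytesIO(raw))
    if deduplicate:
        # same (c0, m0, repeat) printed in two series -> same physical run
        df = df.drop_duplicates(subset=["c0", "m0", "repeat"], keep="first")
    return SwitchoverDataset.from_dataframe(df)
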