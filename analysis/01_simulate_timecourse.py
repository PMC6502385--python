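#!/usr/bin/env python
"""Simulate the clock reaction at the reference parameter point.

Integrates the dimensionless system at (rho, eps, phi) = (2, 1e-3, 0.2)
with the stiff solver, detects the switchover numerically, and writes the
trajectory table.  The run shows the three-phase structure: a fast initial
adjustment in which the iodine fraction collapses from phi to O(eps), a
long induction plateau while vitamin C drains linearly, and a sharp rise
of iodine once the inhibitor is exhausted — the visible colour change.
"""

from pathlib import Path

import vitcclock as vc

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    groups = vc.DimensionlessGroups(rho=2.0, eps=1e-3, phi=0.2)
    tau_sw = vc.switchover_tau(groups)
    traj = vc.simulate(groups, (0.0, 2.0 * tau_sw))
    detected = vc.detect_switchover(traj)

    OUT.mkdir(exist_ok=True)
    traj.to_dataframe().to_csv(OUT / "timecourse.csv", index=False)

    print(f"asymptotic switchover time:  tau = {tau_sw:.2f}")
    print(f"numerically detected:        tau = {detected:.2f} "
          f"({100 * abs(detected - tau_sw) / tau_sw:.1f}% from the formula; "
          "the offset is the O(sqrt(eps)) corner width)")
    print(f"final iodine fraction beta = {traj.beta[-1]:.3f} (equilibrium 0.5, "
          "approached only algebraically)")
    print(f"wrote {OUT / 'timecourse.csv'}")


if __name__ == "__main__":
    main()
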