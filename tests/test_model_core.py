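"""Unit and property tests for the ODE model, integration and detection."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import vitcclock as vc
from vitcclock.exceptions import (
    ClockValidationError,
    InvalidStateError,
    SwitchoverNotReachedError,
)

CONC = st.floats(min_value=0.0, max_value=1e3, allow_nan=False)
POS = st.floats(min_value=1e-6, max_value=1e3, allow_nan=False)


def hand_rates(a, b, c, k0, k1):
    # independent spelling of the mass-action laws, kept deliberately naive
    r_slow = k0 * a**2
    r_fast = k1 * b * c
    return (2 * r_fast - 2 * r_slow, r_slow - r_fast, -r_fast)


class TestRhsDimensional:
    @pytest.mark.parametrize(
        "state,k0,k1",
        [
            ((0.0, 0.0, 0.0), 1.0, 10.0),
            ((2e-3, 0.0, 0.0), 0.5, 500.0),  # only the slow reaction active
            ((1e-3, 1e-3, 1e-3), 0.5, 500.0),
            ((0.3, 0.1, 0.2), 2.0, 50.0),
        ],
    )
    def test_matches_hand_coded_rates(self, state, k0, k1):
        p = vc.KineticParameters(k0=k0, k1=k1, a0=1.0, b0=0.0, c0=1.0)
        assert vc.rhs_dimensional(state, p) == pytest.approx(
            hand_rates(*state, k0, k1), rel=1e-14, abs=0.0
        )

    def test_origin_is_stationary(self):
        p = vc.KineticParameters(k0=3.0, k1=7.0, a0=1.0, b0=0.0, c0=1.0)
        assert vc.rhs_dimensional((0, 0, 0), p) == (0.0, 0.0, 0.0)

    def test_no_inhibitor_leaves_only_slow_reaction(self):
        p = vc.KineticParameters(k0=0.5, k1=500.0, a0=1.0, b0=0.0, c0=1.0)
        da, db, dc = vc.rhs_dimensional((2e-3, 5e-4, 0.0), p)
        assert da == pytest.approx(-2 * 0.5 * (2e-3) ** 2)
        assert db == pytest.approx(0.5 * (2e-3) ** 2)
        assert dc == 0.0

    @given(a=CONC, b=CONC, c=CONC, k0=POS, k1=POS)
    def test_iodine_atoms_conserved_exactly(self, a, b, c, k0, k1):
        p = vc.KineticParameters(k0=k0, k1=k1, a0=1.0, b0=0.0, c0=1.0)
        da, db, _ = vc.rhs_dimensional((a, b, c), p)
        assert da + 2.0 * db == 0.0

    def test_negative_state_rejected(self):
        p = vc.KineticParameters(k0=1.0, k1=10.0, a0=1.0, b0=0.0, c0=1.0)
        with pytest.raises(InvalidStateError):
            vc.rhs_dimensional((-1e-3, 0.0, 0.0), p)


class TestRhsDimensionless:
    def test_equilibrium_is_stationary(self, reference_groups):
        assert vc.rhs_dimensionless((0.5, 0.0), reference_groups) == (0.0, 0.0)

    def test_zero_beta_leaves_production_only(self, reference_groups):
        db, dg = vc.rhs_dimensionless((0.0, 0.7), reference_groups)
        assert db == pytest.approx(reference_groups.eps * reference_groups.rho)
        assert dg == 0.0

    def test_hand_substitution(self):
        g = vc.DimensionlessGroups(rho=2.0, eps=0.01, phi=0.2)
        db, dg = vc.rhs_dimensionless((0.1, 0.5), g)
        assert db == pytest.approx(-0.05 + 0.02 * 0.64)
        assert dg == pytest.approx(-0.1)


class TestNondimensionalize:
    def test_worked_example(self):
        p = vc.KineticParameters(k0=1.0, k1=1000.0, a0=0.6, b0=0.2, c0=0.5)
        g = vc.nondimensionalize(p)
        assert g.rho == pytest.approx(2.0)
        assert g.eps == pytest.approx(1e-3)
        assert g.phi == pytest.approx(0.2)
        assert g.time_scale == pytest.approx(1.0 / (1000.0 * 0.5))

    def test_no_initial_iodine_means_phi_zero(self):
        p = vc.KineticParameters(k0=1.0, k1=1000.0, a0=0.5, b0=0.0, c0=0.5)
        assert vc.nondimensionalize(p).phi == 0.0

    def test_table_row_rho(self):
        p = vc.KineticParameters(
            k0=0.57, k1=570.0, a0=0.0068718, b0=0.0, c0=0.0032630
        )
        assert vc.nondimensionalize(p).rho == pytest.approx(2.106, abs=5e-4)

    @given(
        k0=POS,
        k1=POS,
        a0=st.floats(min_value=1e-6, max_value=10.0),
        b0=st.floats(min_value=0.0, max_value=2.0),
        c0=POS,
    )
    def test_round_trip_identity(self, k0, k1, a0, b0, c0):
        p = vc.KineticParameters(k0=k0, k1=k1, a0=a0, b0=b0, c0=c0)
        q = vc.dimensionalize(vc.nondimensionalize(p))
        for name in ("k0", "k1", "a0", "b0", "c0"):
            assert getattr(q, name) == pytest.approx(getattr(p, name), rel=1e-12)

    def test_error_names_offending_field(self):
        with pytest.raises(ClockValidationError, match="c0"):
            vc.KineticParameters(k0=1.0, k1=1.0, a0=1.0, b0=0.0, c0=0.0)


class TestGroupsValidation:
    def test_phi_range_enforced(self):
        with pytest.raises(ClockValidationError):
            vc.DimensionlessGroups(rho=1.0, eps=1e-3, phi=0.6)

    def test_outside_asymptotic_regime_warns_not_raises(self):
        with pytest.warns(UserWarning, match="rho.*phi"):
            vc.DimensionlessGroups(rho=4.0, eps=1e-3, phi=0.3)
        with pytest.warns(UserWarning, match="not small"):
            vc.DimensionlessGroups(rho=1.0, eps=0.5, phi=0.1)


class TestSimulate:
    def test_slow_reaction_off_keeps_beta_constant(self):
        g = vc.DimensionlessGroups(rho=2.0, eps=0.0, phi=0.2)
        traj = vc.simulate(g, (0.0, 50.0), initial=(0.2, 0.0))
        assert np.allclose(traj.beta, 0.2, atol=1e-9)

    def test_conservation_of_iodine_atoms(self, reference_groups):
        traj = vc.simulate(reference_groups, (0.0, 300.0))
        m0 = 1.0  # dimensionless: a/m0 = 1 - 2*beta, b/m0 = beta
        a_over_m0 = 1.0 - 2.0 * traj.beta
        assert np.max(np.abs(a_over_m0 + 2.0 * traj.beta - m0)) <= 1e-9 * m0

    def test_inhibitor_never_increases(self, reference_groups):
        traj = vc.simulate(reference_groups, (0.0, 300.0))
        assert np.all(np.diff(traj.gamma) <= 1e-10)

    def test_beta_bounded_by_equilibrium(self, reference_groups):
        traj = vc.simulate(reference_groups, (0.0, 2000.0))
        assert np.max(traj.beta) <= 0.5 + 1e-8

    def test_agrees_with_fixed_step_reference(self, rk4):
        g = vc.DimensionlessGroups(rho=2.0, eps=0.01, phi=0.2)
        traj = vc.simulate(g, (0.0, 14.0))
        ts, ys = rk4(
            lambda y: np.array(vc.rhs_dimensionless(y, g)), (g.phi, 1.0), 14.0, 1e-3
        )
        pick = slice(None, None, 1000)  # compare every tau = 1.0
        beta_ref, gamma_ref = ys[pick, 0], ys[pick, 1]
        beta_num, gamma_num = traj.dense(ts[pick])
        assert np.max(np.abs(beta_num - beta_ref) / np.abs(beta_ref + 1e-300)) < 1e-6
        assert np.max(np.abs(gamma_num - gamma_ref) / np.abs(gamma_ref)) < 1e-6

    def test_early_flow_conserves_rho_beta_minus_gamma(self, reference_groups):
        # leading-order region-I invariant, checked over the first 1% of
        # the induction window; its drift is bounded by eps*rho**2*tau
        g = reference_groups
        tau_end = 0.01 * 150.0
        traj = vc.simulate(g, (0.0, tau_end))
        q = g.rho * traj.beta - traj.gamma
        drift_bound = 1.1 * g.eps * g.rho**2 * tau_end
        assert np.max(np.abs(q - q[0])) <= drift_bound

    def test_bad_span_rejected(self, reference_groups):
        with pytest.raises(ClockValidationError):
            vc.simulate(reference_groups, (10.0, 1.0))


class TestDetectSwitchover:
    def test_lands_near_asymptotic_switchover(self, reference_groups):
        traj = vc.simulate(reference_groups, (0.0, 300.0))
        tau_sw = vc.detect_switchover(traj)
        assert tau_sw == pytest.approx(150.0, rel=0.10)

    def test_halving_eps_doubles_switchover(self):
        taus = {}
        for eps in (1e-3, 5e-4):
            g = vc.DimensionlessGroups(rho=2.0, eps=eps, phi=0.2)
            traj = vc.simulate(g, (0.0, 2.5 * vc.switchover_tau(g)))
            taus[eps] = vc.detect_switchover(traj)
        assert taus[5e-4] / taus[1e-3] == pytest.approx(2.0, rel=0.05)

    def test_initial_transient_excluded(self, reference_groups):
        # beta starts at phi = 0.2, above an explicit 0.1 threshold, and
        # falls through it; only the later up-crossing counts
        traj = vc.simulate(reference_groups, (0.0, 400.0))
        tau_sw = vc.detect_switchover(traj, threshold=0.1)
        tau_min = traj.tau[np.argmin(traj.beta)]
        assert tau_sw > tau_min
        assert float(traj.dense(tau_sw)[0]) == pytest.approx(0.1, rel=1e-6)

    def test_window_too_short_raises(self, reference_groups):
        traj = vc.simulate(reference_groups, (0.0, 50.0))
        with pytest.raises(SwitchoverNotReachedError):
            vc.detect_switchover(traj)

    def test_scaled_switchover_converges_to_matched_limit(self):
        # tau_sw(eps)*eps*rho**2 -> 1 - rho*phi as eps -> 0
        errs = []
        for eps in (1e-2, 1e-3, 1e-4):
            g = vc.DimensionlessGroups(rho=2.0, eps=eps, phi=0.2)
            traj = vc.simulate(g, (0.0, 2.5 * vc.switchover_tau(g)))
            scaled = vc.detect_switchover(traj) * eps * g.rho**2
            errs.append(abs(scaled - 0.6))
        assert errs[0] > errs[1] > errs[2]
        assert errs[2] < 0.01


class TestEquilibrium:
    @given(rho=st.floats(min_value=1e-3, max_value=50.0, allow_nan=False))
    def test_closed_form_for_random_rho(self, rho):
        g = vc.DimensionlessGroups(rho=rho, eps=1e-3, phi=0.0)
        rep = vc.equilibrium_analysis(g)
        assert rep.state == (0.5, 0.0)
        assert rep.eigenvalues == (0.0, -rho / 2.0)
        assert rep.eigenvectors == ((1.0, 0.0), (1.0, rho))
        assert rep.manifold_labels == ("slow", "stable")


class TestQuasiSteadyCurve:
    def test_vanishes_at_equilibrium_beta(self, reference_groups):
        assert vc.quasi_steady_curve([0.5], reference_groups)[0] == 0.0

    def test_hand_value(self):
        g = vc.DimensionlessGroups(rho=2.0, eps=0.01, phi=0.2)
        assert vc.quasi_steady_curve([0.1], g)[0] == pytest.approx(0.128)

    def test_beta_zero_reports_infinity(self, reference_groups):
        assert np.isinf(vc.quasi_steady_curve([0.0], reference_groups)[0])

    def test_intersects_simulated_induction_segment(self, reference_groups):
        traj = vc.simulate(reference_groups, (0.0, 300.0))
        mid = (traj.tau > 40) & (traj.tau < 120)  # deep induction
        gamma_pred = vc.quasi_steady_curve(traj.beta[mid], reference_groups)
        # quasi-steadiness holds to a relative accuracy of O(eps)/gamma
        assert np.max(np.abs(gamma_pred - traj.gamma[mid])) < 50 * reference_groups.eps
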