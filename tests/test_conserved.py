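"""Ligand-conserved (buffered) regime: exact n = 1 solution and pooled multisite."""

import numpy as np
import pytest
from scipy.optimize import brentq
from scipy.special import comb

from multikin import identical as ident
from multikin.conserved import (
    ConservedSystem,
    TotalLigandJump,
    aux_C,
    aux_F,
    ec50_conserved,
    form_timecourse_conserved,
    jump_single_timecourse,
    mean_field_site_probabilities,
    steady_form_conserved,
    steady_single,
    tau_half_conserved,
    tau_m_max_conserved,
    u_max_conserved,
)
from multikin.identical import MONOTONIC
from multikin.oracle import integrate_conserved


def test_aux_F_stable_form_matches_definition():
    for ut in (0.0, 0.5, 3.0, 200.0):
        for lt in (1e-6, 2.0, 50.0):
            direct = np.sqrt((ut - lt) ** 2 + 2 * (ut + lt) + 1)
            assert aux_F(ut, lt) == pytest.approx(direct, rel=1e-14)
            assert aux_F(ut, lt) >= abs(ut - lt)


def test_aux_C_singular_without_jump():
    with pytest.raises(ZeroDivisionError):
        aux_C(1.0, 1.0, 2.0)


class TestSteadySingle:
    def test_worked_value(self):
        # L_T/K = 2, U_T/K = 1: L1/K = (1/2)(2+1+1-sqrt(8))
        system = ConservedSystem(n=1, L_T=2.0)
        L0, L1, U = steady_single(system, 1.0)
        assert L1 == pytest.approx(0.5 * (4 - np.sqrt(8)), rel=1e-12)
        assert U == pytest.approx(1.0 - L1, rel=1e-12)

    def test_self_consistency_with_mass_action(self):
        system = ConservedSystem(n=1, L_T=5.0, K=2.0)
        for U_T in (0.1, 1.0, 10.0, 100.0):
            L0, L1, U = steady_single(system, U_T)
            assert L1 == pytest.approx(system.L_T * U / (system.K + U), rel=1e-10)
            assert U + L1 == pytest.approx(U_T, rel=1e-10)

    def test_limits(self):
        tiny = ConservedSystem(n=1, L_T=1e-12)
        _, L1, U = steady_single(tiny, 3.0)
        assert U == pytest.approx(3.0, rel=1e-9)
        big = ConservedSystem(n=1, L_T=1.0)
        _, L1, _ = steady_single(big, 1e8)
        assert L1 == pytest.approx(1.0, rel=1e-6)


class TestJumpSingle:
    def test_initial_condition_and_conservation(self):
        system = ConservedSystem(n=1, L_T=2.0)
        jump = TotalLigandJump(0.3, 5.0)
        L0, L1, U = jump_single_timecourse(system, jump, 0.0)
        _, L1_eq, _ = steady_single(system, 0.3)
        assert L1 == pytest.approx(L1_eq, rel=1e-10)
        t = np.geomspace(1e-5, 20, 30)
        L0, L1, U = jump_single_timecourse(system, jump, t)
        assert np.max(np.abs(U + L1 - 5.0)) < 1e-10
        assert np.max(np.abs(L0 + L1 - 2.0)) < 1e-10

    def test_converges_to_post_jump_equilibrium(self):
        system = ConservedSystem(n=1, L_T=2.0)
        jump = TotalLigandJump(0.3, 5.0)
        _, L1, _ = jump_single_timecourse(system, jump, 100.0)
        _, L1_eq, _ = steady_single(system, 5.0)
        assert L1 == pytest.approx(L1_eq, rel=1e-10)

    def test_null_jump_constant(self):
        system = ConservedSystem(n=1, L_T=2.0)
        t = np.linspace(0, 5, 7)
        _, L1, _ = jump_single_timecourse(system, TotalLigandJump(1.0, 1.0), t)
        _, L1_eq, _ = steady_single(system, 1.0)
        assert np.allclose(L1, L1_eq, rtol=1e-12)

    def test_exact_against_nonlinear_oracle(self):
        """The tanh-form n = 1 solution is exact, both jump directions."""
        rng = np.random.default_rng(19)
        for _ in range(8):
            system = ConservedSystem(n=1, L_T=float(10.0 ** rng.uniform(-1, 1.5)))
            ut = 10.0 ** rng.uniform(-2, 2, size=2)  # includes downward jumps
            jump = TotalLigandJump(float(ut[0]), float(ut[1]))
            t = np.geomspace(1e-4, 30, 40)
            classes, U_free = integrate_conserved(system, jump, t)
            _, L1, U = jump_single_timecourse(system, jump, t)
            scale = max(system.L_T, jump.U_T1)
            assert np.max(np.abs(classes[1] - L1)) / scale < 1e-8
            assert np.max(np.abs(U_free - U)) / scale < 1e-8

    def test_unbuffered_limit_reduces_to_clamped_site(self):
        system = ConservedSystem(n=1, L_T=1e-8)
        jump = TotalLigandJump(0.1, 10.0)
        eta = np.geomspace(1e-4, 3, 20)
        _, L1, _ = jump_single_timecourse(system, jump, eta)
        clamped = ident.jump_form_timecourse(1, 1, 0.1, 10.0, eta)
        assert np.max(np.abs(L1 / system.L_T - clamped)) < 1e-6


class TestMeanFieldMultisite:
    def test_probabilities_sum_to_one_and_conserve_ligand(self):
        system = ConservedSystem(n=4, L_T=3.0)
        jump = TotalLigandJump(0.1, 20.0)
        t = np.geomspace(1e-5, 30, 40)
        p0, p1, u_free = mean_field_site_probabilities(system, jump, t)
        assert np.max(np.abs(p0 + p1 - 1.0)) < 1e-12
        assert np.max(np.abs(u_free - (20.0 - 4 * 3.0 * p1))) < 1e-10

    def test_n1_reduces_to_single_site_solution(self):
        system = ConservedSystem(n=1, L_T=2.0)
        jump = TotalLigandJump(0.3, 5.0)
        t = np.geomspace(1e-4, 10, 20)
        p0, p1, u_free = mean_field_site_probabilities(system, jump, t)
        _, L1, U = jump_single_timecourse(system, jump, t)
        assert np.max(np.abs(p1 * system.L_T - L1)) < 1e-12
        assert np.max(np.abs(u_free * system.K - U)) < 1e-10

    def test_multisite_matches_nonlinear_chain(self):
        """Pooled construction is exact for identical sites (binomial propagation)."""
        system = ConservedSystem(n=4, L_T=3.0)
        jump = TotalLigandJump(0.1, 20.0)
        t = np.geomspace(1e-4, 30, 50)
        classes, U_free = integrate_conserved(system, jump, t)
        for m in range(5):
            mf = form_timecourse_conserved(system, jump, m, t)
            assert np.max(np.abs(classes[m] / (comb(4, m) * system.L_T) - mf)) < 1e-7

    def test_strong_buffering_depletes_free_ligand(self):
        """L_T/K = 50 exhausts free ligand early; L_T/K = 2 barely alters it."""
        jump = TotalLigandJump(0.01, 200.0)
        eta = np.geomspace(1e-4, 0.05, 20)
        _, _, u_weak = mean_field_site_probabilities(
            ConservedSystem(n=4, L_T=2.0), jump, eta
        )
        _, _, u_strong = mean_field_site_probabilities(
            ConservedSystem(n=4, L_T=50.0), jump, eta
        )
        assert np.all(u_strong < u_weak)

    def test_strongest_deficit_in_high_occupancy_forms(self):
        """Buffering hits the 3- and 4-bound conformations hardest (L_T/K = 50)."""
        system = ConservedSystem(n=4, L_T=50.0)
        U_T1 = 200.0
        deficits = []
        for m in range(5):
            buffered = steady_form_conserved(system, m, U_T1)
            unbuffered = ident.steady_form(4, m, U_T1)
            deficits.append((unbuffered - buffered) / max(unbuffered, 1e-300))
        assert max(deficits[3], deficits[4]) > max(deficits[0], deficits[1], deficits[2])


class TestSteadyConserved:
    def test_zero_ligand_all_apo(self):
        system = ConservedSystem(n=4, L_T=3.0)
        assert steady_form_conserved(system, 0, 0.0) == pytest.approx(1.0)
        assert steady_form_conserved(system, 2, 0.0) == 0.0

    def test_unbuffered_limit(self):
        system = ConservedSystem(n=4, L_T=1e-8)
        for u in (0.1, 1.0, 10.0):
            for m in range(5):
                assert steady_form_conserved(system, m, u) == pytest.approx(
                    ident.steady_form(4, m, u), rel=1e-6, abs=1e-12
                )

    def test_endpoint_consistency_with_timecourse(self):
        system = ConservedSystem(n=4, L_T=3.0)
        jump = TotalLigandJump(0.1, 20.0)
        for m in range(5):
            late = form_timecourse_conserved(system, jump, m, 1e3)
            assert late == pytest.approx(
                steady_form_conserved(system, m, 20.0), rel=1e-8, abs=1e-14
            )


class TestConservedMetrics:
    def test_u_max_conserved_values(self):
        system = ConservedSystem(n=4, L_T=3.0)
        assert u_max_conserved(system, 3) == pytest.approx(12.0)
        assert u_max_conserved(system, 1) == pytest.approx(10 / 3)
        tiny = ConservedSystem(n=4, L_T=1e-12)
        assert u_max_conserved(tiny, 3) == pytest.approx(3.0)
        with pytest.raises(ValueError):
            u_max_conserved(system, 0)

    def test_peak_value_equals_unbuffered_peak(self):
        """Buffering shifts the peak position but not its height."""
        system = ConservedSystem(n=4, L_T=3.0)
        for m in (1, 2, 3):
            ut_star = u_max_conserved(system, m)
            assert steady_form_conserved(system, m, ut_star) == pytest.approx(
                ident.n_max(4, m), rel=1e-12
            )
            # numeric argmax confirmation
            ut = np.geomspace(0.05, 100, 4000)
            vals = steady_form_conserved(system, m, ut)
            assert abs(ut[np.argmax(vals)] - ut_star) / ut_star < 1e-2

    def test_ec50_conserved_reduction_and_monotonicity(self):
        tiny = ConservedSystem(n=4, L_T=1e-9)
        assert ec50_conserved(tiny) == pytest.approx(ident.ec50(4), rel=1e-6)
        # n = 1, L_T/K = 2: U_0_half = (1 - 0.5)(1*2 + 1/0.5) = 2
        assert ec50_conserved(ConservedSystem(n=1, L_T=2.0))[0] == pytest.approx(2.0)
        # root-finding confirmation on the steady apo form
        system = ConservedSystem(n=4, L_T=3.0)
        u0h, unh = ec50_conserved(system)
        root = brentq(lambda ut: steady_form_conserved(system, 0, ut) - 0.5, 1e-6, 1e3)
        assert u0h == pytest.approx(root, rel=1e-8)
        # both EC50s strictly increase with protein (buffer) level
        levels = [ec50_conserved(ConservedSystem(n=4, L_T=lt)) for lt in (0.1, 1.0, 10.0)]
        assert levels[0][0] < levels[1][0] < levels[2][0]
        assert levels[0][1] < levels[1][1] < levels[2][1]

    def test_tau_m_max_matches_trajectory_argmax(self):
        system = ConservedSystem(n=4, L_T=3.0)
        jump = TotalLigandJump(0.1, 20.0)
        eta = np.geomspace(1e-6, 50, 100_000)
        for m in (1, 2, 3):
            eta_star = tau_m_max_conserved(system, jump, m)
            assert eta_star != MONOTONIC
            tc = form_timecourse_conserved(system, jump, m, eta)
            assert abs(eta[np.argmax(tc)] - eta_star) < 1e-3 * (1 + eta_star)

    def test_tau_m_max_sentinel_below_asymptote(self):
        system = ConservedSystem(n=4, L_T=3.0)
        # q_3 = 3*(3 + 1) = 12: below it N_3 rises monotonically
        assert tau_m_max_conserved(system, TotalLigandJump(0.1, 11.0), 3) == MONOTONIC
        assert tau_m_max_conserved(system, TotalLigandJump(0.1, 13.0), 3) != MONOTONIC

    def test_tau_m_max_unbuffered_limit(self):
        tiny = ConservedSystem(n=4, L_T=1e-6)
        jump = TotalLigandJump(0.1, 10.0)
        for m in (1, 2):
            conserved_eta = tau_m_max_conserved(tiny, jump, m)
            abundant_eta = ident.tau_m_max(4, m, 0.1, 10.0)
            assert conserved_eta == pytest.approx(abundant_eta, rel=1e-4)

    def test_tau_half_matches_trajectory_crossing(self):
        system = ConservedSystem(n=4, L_T=3.0)
        jump = TotalLigandJump(0.1, 20.0)
        for which, m in (("apo", 0), ("saturated", 4)):
            eta_star = tau_half_conserved(system, jump, which)
            target = 0.5 * (
                form_timecourse_conserved(system, jump, m, 0.0)
                + steady_form_conserved(system, m, 20.0)
            )
            val = form_timecourse_conserved(system, jump, m, eta_star)
            assert val == pytest.approx(target, rel=1e-8)

    def test_tau_half_apo_monotone_saturated_distorted_bell(self):
        system = ConservedSystem(n=4, L_T=3.0)
        ut1 = np.geomspace(1.0, 1e3, 150)
        apo = np.array([
            tau_half_conserved(system, TotalLigandJump(0.1, float(u)), "apo")
            for u in ut1
        ])
        assert np.all(np.diff(apo) < 0)
        sat = np.array([
            tau_half_conserved(system, TotalLigandJump(0.1, float(u)), "saturated")
            for u in ut1
        ])
        k = int(np.argmax(sat))
        assert 0 < k < len(sat) - 1  # interior maximum (distorted bell)


def test_system_validation():
    with pytest.raises(ValueError):
        ConservedSystem(n=0)
    with pytest.raises(ValueError):
        ConservedSystem(n=4, L_T=-1.0)
    with pytest.raises(ValueError):
        TotalLigandJump(-0.1, 1.0)
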