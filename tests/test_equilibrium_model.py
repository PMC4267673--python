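"""Closed-form transfer functions, mass-action oracle and dynamics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from luxfer.equilibrium_model import (
    DeviceParams,
    EquilibriumConstants,
    HyperbolicParams,
    RateConstants,
    SpeciesState,
    basal_output,
    closed_form_sL,
    dimer_partition,
    equilibrium_oracle,
    leaky_coefficients,
    leaky_transfer,
    max_output,
    observables,
    simple_gmax,
    simple_kapp,
    simple_transfer,
    simulate_dynamics,
    steady_state_output,
)

from conftest import SIMPLE_SIM, SHARED_FIT, shared_fit_device


class TestSimpleModel:
    """The leak-free model collapses to Michaelis-Menten apparent parameters."""

    def test_gmax_vanishes_without_receptor(self, simple_sim_device):
        assert simple_gmax(0.0, simple_sim_device, SIMPLE_SIM["K3"]) == 0.0

    def test_gmax_saturates_at_machinery_efficiency(self, simple_sim_device):
        assert simple_gmax(1e9, simple_sim_device, SIMPLE_SIM["K3"]) == pytest.approx(100.0, rel=1e-6)

    def test_gmax_at_unit_phi(self, simple_sim_device):
        # V*phi/((K3 r')^-1 + phi) = 100/(0.01 + 1)
        assert simple_gmax(1.0, simple_sim_device, SIMPLE_SIM["K3"]) == pytest.approx(99.0099, rel=1e-5)

    def test_gmax_degenerate_zero_over_zero_warns_and_returns_limit(self):
        dp = DeviceParams(phi=0.0, r_prime=1.0, V=10.0)
        with pytest.warns(RuntimeWarning):
            assert simple_gmax(0.0, dp, 0.0) == 0.0

    def test_kapp_at_zero_phi_is_intrinsic_dissociation_constant(self):
        assert simple_kapp(0.0, SIMPLE_SIM["K1"], SIMPLE_SIM["K3"], SIMPLE_SIM["r_prime"]) == pytest.approx(5.0)

    def test_kapp_at_unit_phi(self):
        assert simple_kapp(1.0, SIMPLE_SIM["K1"], SIMPLE_SIM["K3"], SIMPLE_SIM["r_prime"]) == pytest.approx(0.049505, rel=1e-4)

    def test_kapp_vanishes_at_saturating_phi(self):
        assert simple_kapp(1e12, SIMPLE_SIM["K1"], SIMPLE_SIM["K3"], SIMPLE_SIM["r_prime"]) == pytest.approx(0.0, abs=1e-12)

    def test_kapp_requires_positive_K1(self):
        with pytest.raises(ValueError):
            simple_kapp(1.0, 0.0, 1.0, 1.0)

    def test_transfer_zero_ligand_gives_zero(self, simple_sim_device):
        assert simple_transfer(0.0, 1.0, simple_sim_device, SIMPLE_SIM["K1"], SIMPLE_SIM["K3"]) == 0.0

    def test_transfer_half_saturates_at_kapp(self, simple_sim_device):
        ka = simple_kapp(1.0, SIMPLE_SIM["K1"], SIMPLE_SIM["K3"], SIMPLE_SIM["r_prime"])
        gm = simple_gmax(1.0, simple_sim_device, SIMPLE_SIM["K3"])
        assert simple_transfer(ka, 1.0, simple_sim_device, SIMPLE_SIM["K1"], SIMPLE_SIM["K3"]) == pytest.approx(gm / 2)
        assert simple_transfer(ka, 1.0, simple_sim_device, SIMPLE_SIM["K1"], SIMPLE_SIM["K3"]) == pytest.approx(49.50, rel=1e-3)

    def test_transfer_rejects_negative_ligand(self, simple_sim_device):
        with pytest.raises(ValueError):
            simple_transfer(-1.0, 1.0, simple_sim_device, SIMPLE_SIM["K1"], SIMPLE_SIM["K3"])

    def test_monotonicity_in_phi(self, simple_sim_device):
        phis = np.logspace(-4, 3, 40)
        gm = [simple_gmax(p, simple_sim_device, SIMPLE_SIM["K3"]) for p in phis]
        ka = [simple_kapp(p, SIMPLE_SIM["K1"], SIMPLE_SIM["K3"], SIMPLE_SIM["r_prime"]) for p in phis]
        assert np.all(np.diff(gm) >= 0)
        assert np.all(np.diff(ka) <= 0)


class TestLeakyModel:
    def test_phi_zero_gives_flat_curve_at_naked_promoter_leak(self, shared_fit_constants):
        hp = leaky_coefficients(0.0, shared_fit_constants, shared_fit_device(0.0))
        assert hp.a1 == pytest.approx(SHARED_FIT["V0"])
        assert hp.a2 == pytest.approx(SHARED_FIT["K1_inv"])
        assert hp.a3 == pytest.approx(SHARED_FIT["K1_inv"])
        L = np.logspace(-10, -4, 20)
        assert leaky_transfer(L, hp) == pytest.approx([SHARED_FIT["V0"]] * 20)

    def test_weak_construct_affinity_constant(self, shared_fit_constants):
        hp = leaky_coefficients(0.03, shared_fit_constants, shared_fit_device(0.03))
        # 3e-6 * (1 + 5*0.03) / (1 + 500*0.03)
        assert hp.a3 == pytest.approx(2.15625e-7, rel=1e-9)

    def test_requires_positive_K1(self):
        ec = EquilibriumConstants(K1=0.0)
        with pytest.raises(ValueError):
            leaky_coefficients(1.0, ec, DeviceParams())

    @pytest.mark.parametrize("phi", [0.0, 0.03, 0.3, 1.0, 10.0])
    def test_coefficients_reproduce_measurable_limits(self, phi, shared_fit_constants):
        """a1*a2/a3 must equal the basal limit and a1 the maximal limit."""
        dp = shared_fit_device(phi)
        hp = leaky_coefficients(phi, shared_fit_constants, dp)
        assert hp.a1 * hp.a2 / hp.a3 == pytest.approx(basal_output(phi, shared_fit_constants, dp), rel=1e-12)
        assert hp.a1 == pytest.approx(max_output(phi, shared_fit_constants, dp), rel=1e-12)

    def test_identity_sweep_over_random_parameters(self):
        """G0/Gm identities and the half-saturation identity over 1e4 draws."""
        rng = np.random.default_rng(20140917)
        n = 10_000
        phi = 10.0 ** rng.uniform(-3, 1, n)
        V0 = 10.0 ** rng.uniform(-1, 3, n)
        K1 = 10.0 ** rng.uniform(3, 8, n)
        K2r = 10.0 ** rng.uniform(-2, 3, n)
        K3r = 10.0 ** rng.uniform(-2, 4, n)
        eR = 10.0 ** rng.uniform(0, 2, n)
        eL = 10.0 ** rng.uniform(0, 3, n)
        for i in range(n):
            ec = EquilibriumConstants(K1=K1[i], K2=K2r[i], K3=K3r[i])
            dp = DeviceParams(phi=phi[i], r_prime=1.0, V0=V0[i], eps_R=eR[i], eps_L=eL[i])
            hp = leaky_coefficients(phi[i], ec, dp)
            g0 = basal_output(phi[i], ec, dp)
            gm = max_output(phi[i], ec, dp)
            assert abs(hp.a1 * hp.a2 / hp.a3 - g0) <= 1e-12 * g0
            assert abs(hp.a1 - gm) <= 1e-12 * gm
            if hp.a3 > 2 * hp.a2:
                half = leaky_transfer(hp.a3 - 2 * hp.a2, hp)
                assert abs(half - hp.a1 / 2) <= 1e-12 * hp.a1

    def test_reduces_to_simple_model_without_leak_pathways(self):
        """k_m0 -> 0 with K2 = 0 collapses the hyperbola onto Eq-18 form."""
        K1, K3r, V = 1e6, 50.0, 40.0
        # V0*eps_L -> V as the leak vanishes with the induced ceiling held fixed
        for phi in (0.05, 0.3, 1.0):
            eps_L = 1e9
            V0 = V / eps_L
            ec = EquilibriumConstants(K1=K1, K2=0.0, K3=K3r)
            dp = DeviceParams(phi=phi, r_prime=1.0, V0=V0, eps_R=1.0, eps_L=eps_L)
            hp = leaky_coefficients(phi, ec, dp)
            dps = DeviceParams(phi=phi, r_prime=1.0, V=V)
            L = np.logspace(-9, -3, 30)
            expected = simple_transfer(L, phi, dps, K1, K3r)
            np.testing.assert_allclose(leaky_transfer(L, hp), expected, rtol=1e-6)

    def test_transfer_limits_and_flat_case(self, characterized):
        hp = characterized["strong"]
        assert leaky_transfer(0.0, hp) == pytest.approx(hp.a1 * hp.a2 / hp.a3)
        assert leaky_transfer(0.0, hp) == pytest.approx(768.0)
        assert leaky_transfer(1.0, hp) == pytest.approx(3.6e4, rel=1e-6)
        flat = HyperbolicParams(a1=100.0, a2=1e-8, a3=1e-8)
        L = np.logspace(-10, -5, 10)
        assert leaky_transfer(L, flat) == pytest.approx([100.0] * 10)

    def test_monotone_increasing_iff_activating(self, characterized):
        L = np.logspace(-11, -5, 50)
        assert np.all(np.diff(leaky_transfer(L, characterized["medium"])) > 0)
        repressing = HyperbolicParams(a1=100.0, a2=1e-7, a3=1e-9)
        assert np.all(np.diff(leaky_transfer(L, repressing)) < 0)

    def test_observables(self, characterized):
        g0, gm, l05 = observables(characterized["strong"])
        assert l05 == pytest.approx(1.436e-8, rel=1e-9)
        assert leaky_transfer(l05, characterized["strong"]) == pytest.approx(1.8e4)
        assert gm == 3.6e4
        g0w, _, _ = observables(characterized["weak"])
        assert g0w == pytest.approx(4.1e4 * 12.7e-10 / 22.0e-8, rel=1e-12)

    def test_observables_degenerate_cases(self):
        mm = HyperbolicParams(a1=50.0, a2=0.0, a3=1e-8)
        obs = observables(mm)
        assert obs.G0 == 0.0 and obs.L05 == pytest.approx(1e-8)
        basal_heavy = HyperbolicParams(a1=50.0, a2=1e-8, a3=1.5e-8)
        assert observables(basal_heavy).L05 is None


class TestDimerPartition:
    def test_quadratic_root(self):
        R, R2 = dimer_partition(3.0, 1.0)
        assert R == pytest.approx(1.0, rel=1e-12)
        assert R2 == pytest.approx(1.0, rel=1e-12)

    def test_no_dimerization(self):
        assert dimer_partition(7.0, 0.0) == (7.0, 0.0)
        assert dimer_partition(0.0, 5.0) == (0.0, 0.0)

    @given(st.floats(1e-12, 1e3), st.floats(0.0, 1e9))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_conservation(self, R_T, K0):
        R, R2 = dimer_partition(R_T, K0)
        assert R >= 0 and R2 >= 0
        assert R + 2 * R2 == pytest.approx(R_T, rel=1e-12)


class TestEquilibriumOracle:
    EC = EquilibriumConstants(K0=1e6, K1=2e5, K2=3e5, K3=1e6)

    def test_no_binding_pathways_leave_promoter_free(self):
        ec = EquilibriumConstants(K0=1e6, K1=2e5, K2=0.0, K3=1e6)
        st_ = equilibrium_oracle(1e-6, 1e-9, 0.0, ec)
        assert st_.S_L == 0.0 and st_.S_R == 0.0
        assert st_.P == pytest.approx(1e-9)

    def test_no_promoter_still_satisfies_ligand_equilibrium(self):
        st_ = equilibrium_oracle(1e-6, 0.0, 1e-6, self.EC)
        assert st_.P == st_.S_R == st_.S_L == 0.0
        assert st_.Q / (st_.R2 * 1e-6) == pytest.approx(self.EC.K1, rel=1e-9)

    def test_conservation_holds_exactly(self):
        st_ = equilibrium_oracle(5e-7, 2e-9, 1e-7, self.EC)
        assert st_.receptor_total == pytest.approx(5e-7, rel=1e-10)
        assert st_.promoter_total == pytest.approx(2e-9, rel=1e-10)

    @pytest.mark.parametrize("L", [1e-9, 1e-7, 1e-5])
    def test_converges_to_closed_form_under_excess_receptor(self, L):
        """With R_T = 1e4 * P_T the closed form is accurate to < 0.1%."""
        ec = EquilibriumConstants(K0=1e6, K1=2e5, K2=0.0, K3=1e6)
        P_T = 1e-9
        st_ = equilibrium_oracle(1e4 * P_T, P_T, L, ec)
        R2T = st_.R2 + st_.Q + st_.S_R + st_.S_L
        sl = closed_form_sL(R2T, P_T, L, ec.K1, ec.K3)
        assert abs(st_.S_L - sl) / sl < 1e-3


class TestDynamics:
    RC = RateConstants(k_m0=0.01, k_mR=0.05, k_mL=1.0, k_md=0.14, k_p=2.0, k_pd=0.017)
    EC = EquilibriumConstants(K0=1e7, K1=1 / 3e-6, K2=5e6, K3=5e8)
    TOTALS = (1e-5, 1e-9, 1e-6)

    def test_frozen_kinetics_leave_protein_constant(self):
        rc = RateConstants(k_m0=0, k_mR=0, k_mL=0, k_md=0, k_p=0, k_pd=0)
        state0 = SpeciesState(mG=2.0, G=5.0)
        mg, g = simulate_dynamics(state0, rc, self.EC, self.TOTALS, np.linspace(0, 100, 11))
        np.testing.assert_allclose(g, 5.0, rtol=1e-9)
        np.testing.assert_allclose(mg, 2.0, rtol=1e-9)

    def test_naked_promoter_only_matches_linear_ode_solution(self):
        """With binding off, G* = k_p k_m0 P_T / (k_pd k_md)."""
        rc = RateConstants(k_m0=0.2, k_mR=0.0, k_mL=0.0, k_md=0.1, k_p=0.5, k_pd=0.05)
        ec = EquilibriumConstants(K0=0.0, K1=1.0, K2=0.0, K3=0.0)
        P_T = 2e-9
        t = np.linspace(0, 500, 20)
        _, g = simulate_dynamics(SpeciesState(), rc, ec, (0.0, P_T, 0.0), t)
        gstar = rc.k_p * rc.k_m0 * P_T / (rc.k_pd * rc.k_md)
        assert g[-1] == pytest.approx(gstar, rel=1e-6)

    def test_induced_steady_state_proportional_to_active_complex(self):
        """Zero leak rates: G*/S_L = k_p k_mL / (k_pd k_md)."""
        rc = RateConstants(k_m0=0.0, k_mR=0.0, k_mL=1.0, k_md=0.14, k_p=2.0, k_pd=0.017)
        eq = equilibrium_oracle(*self.TOTALS, self.EC)
        t = np.linspace(0, 3000, 30)
        _, g = simulate_dynamics(SpeciesState(), rc, self.EC, self.TOTALS, t)
        assert g[-1] / eq.S_L == pytest.approx(rc.k_p * rc.k_mL / (rc.k_pd * rc.k_md), rel=1e-4)

    def test_long_time_limit_matches_hyperbolic_closed_form(self):
        """ODE endpoint agrees with the leaky hyperbola to < 0.1%."""
        t = np.linspace(0, 2000, 40)
        _, g = simulate_dynamics(SpeciesState(), self.RC, self.EC, self.TOTALS, t)
        gstar = steady_state_output(self.RC, self.EC, self.TOTALS)
        assert abs(g[-1] - gstar) / gstar < 1e-3
        # and the closed-form hyperbola built from the same mechanism agrees
        R_T, P_T, L = self.TOTALS
        eq = equilibrium_oracle(R_T, P_T, L, self.EC)
        R2T = eq.R2 + eq.Q + eq.S_R + eq.S_L
        gamma_g = self.RC.k_p / (self.RC.k_pd * self.RC.k_md)
        dp = DeviceParams(
            phi=1.0,
            r_prime=R2T,
            V0=gamma_g * self.RC.k_m0 * P_T,
            eps_R=self.RC.k_mR / self.RC.k_m0,
            eps_L=self.RC.k_mL / self.RC.k_m0,
        )
        hp = leaky_coefficients(1.0, self.EC, dp)
        assert abs(leaky_transfer(L, hp) - g[-1]) / g[-1] < 1e-3

    def test_rejects_non_monotone_time_grid(self):
        with pytest.raises(ValueError):
            simulate_dynamics(SpeciesState(), self.RC, self.EC, self.TOTALS, [0.0, 10.0, 5.0])
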