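"""Macroscopic mass/mean ODEs, saturated incidence and reproduction number."""

import numpy as np
import pytest

from opikin.equilibrium import BetaEquilibrium
from opikin.macro import (GUARD, SaturatedParams, classical_seir, closure_m2,
                          integrate_macro, macro_rhs, macro_state,
                          polarization_sweep, r0, saturated_mS,
                          saturated_system)
from opikin.seir import EpidemicParams

EPI = EpidemicParams(beta=0.4, alpha=1.0, sigma_e=0.5, gamma=1 / 12)


def default_state(m=(0.0, 0.0, 0.0, 0.0), rho=(0.97, 0.01, 0.01, 0.01)):
    return macro_state(rho, m)


class TestClosure:
    def test_dirac_limit(self):
        assert closure_m2(0.5, 0.3, 0.0) == pytest.approx(0.5 * 0.09)

    def test_worked_value(self):
        assert closure_m2(1.0, 0.0, 2.0) == pytest.approx(0.5)

    @pytest.mark.parametrize("m,nu", [(0.0, 0.5), (0.2, 2.0), (-0.5, 0.1)])
    def test_consistent_with_beta_energy(self, m, nu):
        eq = BetaEquilibrium(m, nu)
        assert closure_m2(0.7, m, nu) == pytest.approx(0.7 * eq.second_moment,
                                                       abs=1e-10)


class TestMacroRHS:
    def test_susceptible_consensus_freezes_mean(self):
        """nu_S = 0: the susceptible mean opinion is an exact invariant."""
        rng = np.random.default_rng(0)
        for _ in range(50):
            m = rng.uniform(-1, 1, 4)
            rho = rng.dirichlet(np.ones(4))
            d = macro_rhs(macro_state(rho, m), EPI, nu_s=0.0)
            assert d[4] == 0.0

    def test_equal_means_freeze_infected_relaxation(self):
        y = default_state(m=(0.1, 0.3, 0.3, 0.0))
        d = macro_rhs(y, EPI, nu_s=0.5)
        assert d[6] == pytest.approx(0.0, abs=1e-15)  # m_E == m_I

    def test_exposed_mean_decreases_under_consensus(self):
        # nu_S = 0 and positive m_E: the exposed mean trajectory decreases
        y = default_state(m=(0.0, 0.4, 0.0, 0.0))
        d = macro_rhs(y, EPI, nu_s=0.0)
        assert d[5] < 0

    def test_empty_compartment_guard(self):
        y = macro_state([0.99, 0.0, 0.01, 0.0], [0.0, 0.2, 0.1, 0.0])
        d = macro_rhs(y, EPI, nu_s=0.5)
        assert d[5] == 0.0 and d[7] == 0.0  # rho_E, rho_R below guard
        assert np.isfinite(d).all()

    def test_incidence_nonnegative(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            m = rng.uniform(-1, 1, 4)
            rho = rng.dirichlet(np.ones(4))
            d = macro_rhs(macro_state(rho, m), EPI, nu_s=1.0)
            assert d[0] <= 0.0  # susceptibles never increase


class TestIntegrateMacro:
    def test_conservation_and_bounds(self):
        y0 = default_state(m=(-0.5, -0.5, 0.5, 0.5))
        times, Y = integrate_macro(y0, EPI, nu_s=1e-3, T=100.0, dt=0.1)
        assert np.max(np.abs(Y[:, :4].sum(axis=1) - 1.0)) < 1e-10
        assert np.all(np.abs(Y[:, 4:]) <= 1.0)
        assert np.all(np.diff(Y[:, 0]) <= 1e-12)   # rho_S non-increasing
        assert np.all(np.diff(Y[:, 3]) >= -1e-12)  # rho_R non-decreasing
        assert np.all(np.diff(Y[:, 4]) >= -1e-14)  # m_S non-decreasing

    def test_beta_zero_freezes_masses_and_ms(self):
        y0 = default_state(m=(0.3, 0.1, 0.2, 0.0))
        params = EpidemicParams(beta=0.0, alpha=1.0, sigma_e=0.5, gamma=1 / 12)
        _, Y = integrate_macro(y0, params, nu_s=1.0, T=10.0, dt=0.01)
        assert np.max(np.abs(Y[:, 0] - Y[0, 0])) < 1e-14
        assert np.max(np.abs(Y[:, 4] - Y[0, 4])) < 1e-14

    def test_consensus_invariant_along_trajectory(self):
        y0 = default_state(m=(0.5, 0.5, 0.5, 0.5))
        _, Y = integrate_macro(y0, EPI, nu_s=0.0, T=50.0, dt=0.01)
        assert np.max(np.abs(Y[:, 4] - 0.5)) == 0.0


class TestSaturatedIncidence:
    PARAMS = SaturatedParams(beta=0.4, sigma_e=0.5, gamma=1 / 12,
                             m_bar_i=0.3, m_s0=-0.2, nu_s=2.0)

    def test_initial_value_identity(self):
        assert saturated_mS(0.0, self.PARAMS, (np.array([0.0, 1.0]),
                                               np.array([0.1, 0.1]))) == \
            pytest.approx(self.PARAMS.m_s0)

    def test_logistic_limit(self):
        # a huge accumulated exposure saturates the mean at +1
        s = np.linspace(0, 1e5, 2001)
        out = saturated_mS(1e5, self.PARAMS, (s, np.full_like(s, 0.5)))
        assert out == pytest.approx(1.0, abs=1e-6)

    def test_frozen_branch_at_extreme_start(self):
        params = SaturatedParams(beta=0.4, sigma_e=0.5, gamma=1 / 12,
                                 m_bar_i=0.3, m_s0=1.0, nu_s=2.0)
        assert saturated_mS(3.0, params, (np.array([0.0, 5.0]),
                                          np.array([0.2, 0.2]))) == 1.0

    def test_closed_form_matches_rk4_oracle(self):
        """Logistic formula vs direct RK4 of the mean ODE on a fixed path."""
        rho = lambda s: 0.05 * np.exp(-((s - 30) / 15) ** 2)
        s = np.linspace(0, 100, 20001)
        t_eval = s[::10]
        closed = saturated_mS(t_eval, self.PARAMS, (s, rho(s)))

        m, dt, out = self.PARAMS.m_s0, s[1] - s[0], [self.PARAMS.m_s0]
        f = lambda t, m: self.PARAMS.j_rate(rho(t)) * (1 - m**2)
        for k in range(len(s) - 1):
            t = k * dt
            k1 = f(t, m); k2 = f(t + dt / 2, m + dt / 2 * k1)
            k3 = f(t + dt / 2, m + dt / 2 * k2); k4 = f(t + dt, m + dt * k3)
            m = m + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
            out.append(m)
        reference = np.array(out)[::10]
        rel = np.max(np.abs(closed - reference) / np.maximum(np.abs(reference), 1e-10))
        assert rel < 1e-6

    def test_system_matches_pinned_mean_macro(self):
        """Two routes to the reduced model agree to RK4 accuracy."""
        rho0 = [0.97, 0.01, 0.01, 0.01]
        frame = saturated_system(rho0, self.PARAMS, T=100.0, dt=0.01)
        y0 = macro_state(rho0, [self.PARAMS.m_s0] * 4)
        _, Y = integrate_macro(y0, self.PARAMS.epidemic_params(),
                               self.PARAMS.nu_s, 100.0, 0.01,
                               pinned_m_i=self.PARAMS.m_bar_i)
        for i, c in enumerate(["rho_S", "rho_E", "rho_I", "rho_R"]):
            assert np.max(np.abs(frame[c].values - Y[:, i])) < 1e-6

    def test_effective_rate_stays_in_unit_interval(self):
        frame = saturated_system([0.97, 0.01, 0.01, 0.01], self.PARAMS,
                                 T=100.0, dt=0.01)
        beta_h = self.PARAMS.beta_bar * frame["H"].values
        assert np.all(beta_h > 0.0) and np.all(beta_h < 1.0)
        assert np.all(np.diff(frame["m_S"].values) >= -1e-14)

    def test_consensus_reduces_to_constant_rate_seir(self):
        params = SaturatedParams(beta=0.4, sigma_e=0.5, gamma=1 / 12,
                                 m_bar_i=0.3, m_s0=-0.2, nu_s=0.0)
        rho0 = [0.97, 0.01, 0.01, 0.01]
        frame = saturated_system(rho0, params, T=50.0, dt=0.01)
        # H frozen at 1 - m_s0: same as classical SEIR with that rate
        eff = EpidemicParams(beta=params.beta_bar * (1 - params.m_s0),
                             sigma_e=params.sigma_e, gamma=params.gamma)
        _, R = classical_seir(rho0, eff, 50.0, 0.01)
        assert np.max(np.abs(frame[["rho_S", "rho_E", "rho_I", "rho_R"]].values
                             - R)) < 1e-10


class TestReproductionNumber:
    def test_formula(self):
        assert r0(0.4, 0.0, 1 / 12) == pytest.approx(1.2)
        assert r0(0.4, 1.0, 1 / 12) == 0.0
        with pytest.raises(ValueError):
            r0(0.4, 0.0, 0.0)

    @pytest.mark.parametrize("gamma,expect_growth", [(1 / 12, True), (1 / 3, False)])
    def test_threshold_matches_linearized_growth(self, gamma, expect_growth):
        """R0 > 1 iff the disease-free state is linearly unstable iff an
        almost-disease-free trajectory initially grows."""
        # m_bar_i = 0.1: R0 = 0.4*0.9/(4*gamma) = 1.08 (gamma=1/12) or 0.27
        params = SaturatedParams(beta=0.4, sigma_e=0.5, gamma=gamma,
                                 m_bar_i=0.1, m_s0=0.0, nu_s=0.0)
        R0_eff = r0(params.beta, params.m_bar_i, params.gamma)  # m_s0=0, rho_S0~1
        assert (R0_eff > 1.0) is expect_growth
        # linearized infection subsystem at the disease-free state
        jac = np.array([[-params.sigma_e, params.beta_bar * (1 - params.m_s0)],
                        [params.sigma_e, -params.gamma]])
        lead = np.max(np.linalg.eigvals(jac).real)
        assert bool(lead > 0) is expect_growth
        # simulated growth of the infected pressure rho_E + rho_I (the
        # horizon is long because R0 = 1.08 is only mildly supercritical)
        frame = saturated_system([1 - 1e-6, 0.0, 1e-6, 0.0], params,
                                 T=500.0, dt=0.05)
        pressure = frame["rho_E"].values + frame["rho_I"].values
        assert bool(pressure[-1] > pressure[0]) is expect_growth


class TestPolarizationSweep:
    def test_monotone_in_nu(self):
        nu_grid = np.linspace(0.0, 10.0, 6)
        up = polarization_sweep(nu_grid, 0.5, EPI, T=150.0)
        down = polarization_sweep(nu_grid, -0.5, EPI, T=150.0)
        assert np.all(np.diff(up["rho_R_T"].values) >= -1e-12)
        assert np.all(np.diff(down["rho_R_T"].values) <= 1e-12)

    def test_consensus_entry_matches_frozen_mean_model(self):
        nu_grid = np.array([0.0])
        table = polarization_sweep(nu_grid, 0.5, EPI, T=150.0)
        # nu_S = 0 keeps every mean at m0; pinned-mean macro run, same grid
        y0 = macro_state([0.97, 0.01, 0.01, 0.01], [0.5] * 4)
        _, Y = integrate_macro(y0, EPI, 0.0, 150.0, 1e-2)
        assert table["rho_R_T"].iloc[0] == pytest.approx(Y[-1, 3], abs=1e-12)

    def test_out_of_range_nu_rejected(self):
        with pytest.raises(ValueError):
            polarization_sweep([12.0], 0.5, EPI)
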