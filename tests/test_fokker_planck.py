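"""Structure-preserving Fokker-Planck solver: conservation, stationarity,
positivity, relaxation and the nonlocal bounded-confidence drift."""

import numpy as np
import pytest

from opikin.equilibrium import BetaEquilibrium
from opikin.fokker_planck import (FokkerPlanckSolver, drift_linear,
                                  drift_nonlocal, relax_to_equilibrium, sp_step)
from opikin.grid import CompartmentDensity, OpinionGrid
from opikin.micro import InteractionKernel, OpinionParams


@pytest.fixture(scope="module")
def grid():
    return OpinionGrid(201)


def uniform_density(grid):
    return np.full(grid.n_nodes, 0.5)


class TestDrifts:
    def test_linear_drift_values(self, grid):
        f = CompartmentDensity(grid, grid.project_piecewise_uniform(
            [(-0.6, 1.0, 0.625)]))
        assert f.mean == pytest.approx(0.2)
        assert drift_linear(f, 1.0, f.mean) == pytest.approx(0.0, abs=1e-12)
        assert drift_linear(f, 1.0, -1.0) == pytest.approx(-1.2)
        assert drift_linear(f, 1.0, 0.5) > 0  # positive above the mean

    def test_zero_mass_density_rejected(self, grid):
        f = CompartmentDensity(grid, np.zeros(grid.n_nodes))
        with pytest.raises(ValueError):
            drift_linear(f, 1.0, 0.0)

    def test_nonlocal_constant_kernel_reduces_to_linear(self, grid):
        f = CompartmentDensity(grid, 0.7 * grid.project_piecewise_uniform(
            [(-0.6, 1.0, 0.625)]))
        nonlocal_drift = drift_nonlocal(f, 0.8, InteractionKernel(), grid.nodes)
        linear_times_mass = drift_linear(f, 0.8, grid.nodes) * f.mass
        np.testing.assert_allclose(nonlocal_drift, linear_times_mass, atol=1e-13)

    def test_zero_confidence_threshold_gives_zero_drift(self, grid):
        f = CompartmentDensity(grid, uniform_density(grid))
        kernel = InteractionKernel(kind="bounded_confidence", delta=0.0)
        assert np.max(np.abs(drift_nonlocal(f, 1.0, kernel, grid.nodes))) == 0.0

    def test_nonlocal_drift_odd_for_symmetric_density(self, grid):
        f = CompartmentDensity(grid, uniform_density(grid))
        kernel = InteractionKernel(kind="bounded_confidence", delta=2.0)
        d = drift_nonlocal(f, 1.0, kernel, grid.nodes)
        np.testing.assert_allclose(d, -d[::-1], atol=1e-13)

    def test_asymmetric_kernel_rejected(self, grid):
        f = CompartmentDensity(grid, uniform_density(grid))
        with pytest.raises(ValueError, match="symmetric"):
            drift_nonlocal(f, 1.0,
                           InteractionKernel(kind="linear_asymmetric", p=0.2, q=0.5),
                           grid.nodes)


class TestStructurePreservation:
    def test_zero_coefficients_leave_density_unchanged(self, grid):
        f = CompartmentDensity(grid, uniform_density(grid))
        out = sp_step(f, OpinionParams(lam=0.0, sigma2=0.0), 0.1)
        np.testing.assert_array_equal(out.values, f.values)

    @pytest.mark.parametrize("nu,m", [(1e-3, 0.2), (0.25, 0.0), (0.25, 0.5),
                                      (2.0, 0.0), (2.0, 0.2), (10.0, -0.5)])
    def test_beta_law_is_discrete_steady_state(self, grid, nu, m):
        """Well-balanced property: frozen-mean residual at solver tolerance.

        The discrete equilibrium is the nodal beta for consensus profiles and
        the cell-averaged beta for polarized (boundary-divergent) ones.
        """
        from opikin.equilibrium import is_polarized
        eq = BetaEquilibrium(m, nu)
        if is_polarized(eq):
            f = eq.cell_averages(grid)
        else:
            f = grid.normalize(eq.density(grid.nodes))
        solver = FokkerPlanckSolver(grid, OpinionParams(lam=1.0, sigma2=nu))
        out = solver.step(f, 0.1, frozen_mean=m)
        assert grid.l1_distance(f, out) <= 1e-10

    @pytest.mark.parametrize("drift_mode,kernel", [
        ("linear", InteractionKernel()),
        ("nonlocal", InteractionKernel(kind="bounded_confidence", delta=0.5)),
    ])
    def test_mass_conserved_every_step(self, grid, drift_mode, kernel):
        params = OpinionParams(lam=1.0, sigma2=0.05, kernel=kernel)
        solver = FokkerPlanckSolver(grid, params, drift_mode=drift_mode)
        f = grid.project_piecewise_uniform([(-0.6, 1.0, 0.625)])
        for _ in range(20):
            f_next = solver.step(f, 0.5)
            assert abs(grid.mass(f_next) - grid.mass(f)) <= 1e-12
            f = f_next

    def test_positivity_preserved_large_steps(self, grid):
        params = OpinionParams(lam=1.0, sigma2=1e-3)
        solver = FokkerPlanckSolver(grid, params, tau=1e-5)
        f = grid.project_piecewise_uniform([(-1.0, 0.0, 1.0)])
        out = solver.step(f, 0.1)  # effective step 1e4
        assert np.all(out >= 0.0)
        assert grid.mass(out) == pytest.approx(1.0, abs=1e-10)

    def test_mean_conserved_frozen_linear(self, grid):
        params = OpinionParams(lam=1.0, sigma2=0.25)
        solver = FokkerPlanckSolver(grid, params)
        f = grid.project_piecewise_uniform([(-0.6, 1.0, 0.625)])
        m0 = grid.mean(f)
        for _ in range(100):
            f = solver.step(f, 0.1, frozen_mean=m0)
        assert grid.mean(f) == pytest.approx(m0, abs=1e-7)

    def test_mean_conserved_bounded_confidence(self, grid):
        kernel = InteractionKernel(kind="bounded_confidence", delta=0.5)
        params = OpinionParams(lam=1.0, sigma2=1e-3, kernel=kernel)
        solver = FokkerPlanckSolver(grid, params, drift_mode="nonlocal")
        f = uniform_density(grid)
        m0 = grid.mean(f)
        for _ in range(200):
            f = solver.step(f, 0.1)
        assert grid.mean(f) == pytest.approx(m0, abs=1e-4)


class TestRelaxation:
    def test_converges_to_beta_with_decreasing_distance(self, grid):
        params = OpinionParams(lam=1.0, sigma2=0.25)
        f0 = CompartmentDensity(grid, uniform_density(grid))
        times, snaps, l1 = relax_to_equilibrium(f0, params, T=10.0, dt=0.1)
        assert l1[-1] < 1e-3
        # monotone decrease until the grid-accuracy floor
        above_floor = l1 > 10 * l1[-1]
        assert np.all(np.diff(l1[above_floor]) < 0)

    def test_mean_trajectory_constant_symmetric_start(self, grid):
        params = OpinionParams(lam=1.0, sigma2=0.25)
        f0 = CompartmentDensity(grid, uniform_density(grid))
        _, snaps, _ = relax_to_equilibrium(f0, params, T=5.0, dt=0.1)
        means = [grid.mean(s) for s in snaps]
        assert max(abs(m - means[0]) for m in means) < 1e-10

    def test_second_moment_matches_closure(self, grid):
        for nu in (0.25, 2.0):
            params = OpinionParams(lam=1.0, sigma2=nu)
            f0 = CompartmentDensity(grid, uniform_density(grid))
            _, snaps, _ = relax_to_equilibrium(f0, params, T=40.0, dt=0.1)
            m2 = grid.moment(snaps[-1], 2)
            assert m2 == pytest.approx(nu / (2 + nu), abs=1e-3)

    def test_bounded_confidence_forms_two_symmetric_clusters(self, grid):
        from opikin.experiments import cluster_count
        kernel = InteractionKernel(kind="bounded_confidence", delta=0.5)
        params = OpinionParams(lam=1.0, sigma2=1e-3, kernel=kernel)
        f0 = CompartmentDensity(grid, uniform_density(grid))
        _, snaps, _ = relax_to_equilibrium(f0, params, T=100.0, dt=0.1,
                                           drift_mode="nonlocal")
        final = snaps[-1]
        assert cluster_count(final) == 2
        from scipy.signal import find_peaks
        peaks, _ = find_peaks(final, prominence=0.05 * final.max())
        locs = grid.nodes[peaks]
        assert locs[0] == pytest.approx(-locs[1], abs=2 * grid.dw)  # symmetric
        assert locs[1] - locs[0] > 0.5  # separated by more than the threshold

    def test_sigma_zero_with_drift_raises(self, grid):
        f = CompartmentDensity(grid, uniform_density(grid))
        with pytest.raises(ValueError):
            sp_step(f, OpinionParams(lam=1.0, sigma2=0.0), 0.1)


class TestTimeSchemes:
    def test_crank_nicolson_is_higher_order(self):
        grid = OpinionGrid(51)
        f0 = grid.normalize(BetaEquilibrium(-0.3, 0.5).density(grid.nodes))
        solver = FokkerPlanckSolver(grid, OpinionParams(lam=0.5, sigma2=0.05))

        def richardson(scheme, dt):
            one = solver.step(f0, dt, scheme=scheme)
            two = solver.step(solver.step(f0, dt / 2, scheme=scheme),
                              dt / 2, scheme=scheme)
            return np.max(np.abs(one - two))

        # halving dt shrinks the defect ~4x more for CN than for implicit Euler
        for scheme, min_ratio in [("semi-implicit", 2.0), ("crank-nicolson", 4.5)]:
            e_coarse = richardson(scheme, 0.05)
            e_fine = richardson(scheme, 0.025)
            assert e_coarse / e_fine > min_ratio

    def test_unknown_scheme_rejected(self, grid):
        solver = FokkerPlanckSolver(grid, OpinionParams(lam=0.5, sigma2=0.05))
        with pytest.raises(ValueError, match="scheme"):
            solver.step(uniform_density(grid), 0.1, scheme="leapfrog")
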