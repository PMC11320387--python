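import warnings

import numpy as np
import pytest

from gelrelease import ddft as D, fields as F
from gelrelease.units import molar_to_number_density

from conftest import probe_molecule, quick_release


class TestExcludedVolume:
    def test_packing_fraction(self):
        assert D.local_packing_fraction(0.0, 0.114) == 0.0
        rho = molar_to_number_density(0.01)
        phi = D.local_packing_fraction(rho, 0.114)
        assert phi == pytest.approx(4 * np.pi / 3 * 0.114**3 * 6.022e-3, rel=1e-3)
        # linearity
        assert D.local_packing_fraction(2 * rho, 0.114) == pytest.approx(2 * phi)
        with pytest.raises(ValueError):
            D.local_packing_fraction(1e3, 1.0)

    def test_carnahan_starling_limits(self):
        assert D.excess_chemical_potential(0.0) == 0.0
        # second-virial limit: slope 8 as phi -> 0
        eps = 1e-8
        assert D.excess_chemical_potential(eps) / eps == pytest.approx(8.0, rel=1e-6)
        phi = np.linspace(0.0, 0.5, 200)
        mu = D.excess_chemical_potential(phi)
        assert np.all(np.diff(mu) > 0)
        with pytest.raises(ValueError):
            D.excess_chemical_potential(1.0)


class TestInitialCondition:
    def test_step_loading(self):
        gel = F.MicrogelSpec(b=10.0, beta_dG=0.0)
        grid = F.build_grid(gel)
        rho0 = molar_to_number_density(0.01)
        assert rho0 == pytest.approx(6.022e-3, rel=1e-4)
        state = D.initial_condition(grid, gel, rho0)
        n0 = float(np.sum(state.density * grid.shell_volumes))
        expected = rho0 * 4 * np.pi / 3 * gel.b**3
        cell_vol = grid.shell_volumes[np.argmin(np.abs(grid.centers - gel.b))]
        assert abs(n0 - expected) < rho0 * cell_vol
        assert state.time == 0.0
        assert np.all(state.density[grid.centers > gel.b] == 0.0)


class TestStepper:
    def test_uniform_equilibrium_fixed_point(self):
        """No potential, uniform D, reflecting walls, uniform density: the
        state must be exactly stationary."""
        gel = F.MicrogelSpec(b=10.0, beta_dG=0.0, R_over_b=3.0)
        grid = F.build_grid(gel, dr_fine=0.1)
        mol = probe_molecule(0.0, 1.0)
        cfg = D.SolverConfig(scheme="explicit", dt=1e-3, outer_bc="reflecting",
                             include_excess=False)
        state = D.CargoState(time=0.0, density=np.full(grid.n_cells, 1.0))
        new = D.step(state, grid, gel, mol, cfg)
        np.testing.assert_allclose(new.density, 1.0, rtol=1e-14)
        assert new.released_accumulator == 0.0

    def test_explicit_stability_bound_enforced(self):
        gel = F.MicrogelSpec(b=10.0, beta_dG=0.0)
        grid = F.build_grid(gel)  # dr_min = 0.02 -> bound 2e-4 tau0
        mol = probe_molecule(0.0, 1.0)
        cfg = D.SolverConfig(scheme="explicit", dt=1e-3)
        state = D.initial_condition(grid, gel, 1.0)
        with pytest.raises(ValueError, match="stability"):
            D.step(state, grid, gel, mol, cfg)

    def test_mass_conservation_explicit(self):
        """Reflecting walls: total cargo conserved to 1e-8 over 1e4 steps."""
        gel = F.MicrogelSpec(b=10.0, beta_dG=-2.0, R_over_b=3.0)
        grid = F.build_grid(gel, dr_fine=0.1)
        mol = probe_molecule(-2.0, 0.1)
        cfg = D.SolverConfig(scheme="explicit", dt=2e-3, outer_bc="reflecting",
                             f_stop=1.0, t_max=2e-3 * 1e4, include_excess=False)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            traj = D.run_release(gel, mol, grid=grid, config=cfg)
        assert traj.meta["steps"] >= 1e4
        assert traj.meta["mass_balance_error"] < 1e-8

    def test_mass_conservation_absorbing_bookkeeping(self):
        """With an absorbing boundary, interior + absorbed stays equal to the
        initial load."""
        traj = quick_release(10.0, -1.0, 0.1)
        assert traj.meta["mass_balance_error"] < 1e-8

    def test_explicit_implicit_agree(self):
        """The two schemes give the same half-release time within 2%."""
        gel = F.MicrogelSpec(b=5.0, beta_dG=0.0, R_over_b=10.0)
        grid = F.build_grid(gel, dr_fine=0.02)
        mol = probe_molecule(0.0, 0.2)
        cfg_e = D.SolverConfig(scheme="explicit", dt=1.5e-4, f_stop=0.6,
                               include_excess=False, output_stride=200)
        cfg_i = D.SolverConfig(scheme="implicit", f_stop=0.6, include_excess=False)
        th_e = D.half_release_time(D.run_release(gel, mol, grid=grid, config=cfg_e))
        th_i = D.half_release_time(D.run_release(gel, mol, grid=grid, config=cfg_i))
        assert th_i == pytest.approx(th_e, rel=0.02)


class TestFreeDiffusionOracle:
    def test_matches_eigenfunction_series(self):
        """Uniform D, no potential, absorbing at R: the density must match
        the classical eigenfunction expansion for release from a sphere."""
        gel = F.MicrogelSpec(b=10.0, beta_dG=0.0, R_over_b=4.0)
        grid = F.build_grid(gel, dr_fine=0.1, dr_coarse=0.1)
        mol = probe_molecule(0.0, 1.0)
        rho0 = molar_to_number_density(0.01)
        for t_end in (5.0, 20.0, 50.0):
            cfg = D.SolverConfig(scheme="explicit", dt=2e-3, f_stop=1.0,
                                 t_max=t_end, include_excess=False,
                                 output_stride=1000)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                traj = D.run_release(gel, mol, grid=grid, config=cfg, rho0=rho0)
            r, t = grid.centers, traj.final_state.time
            R, b = grid.R, gel.b
            n = np.arange(1, 4000)[:, None]
            k = n * np.pi / R
            Bn = (2.0 * rho0 / R) * (np.sin(k * b) - k * b * np.cos(k * b)) / k**2
            rho_series = np.sum(Bn * np.sin(k * r) * np.exp(-(k**2) * t), axis=0) / r
            assert np.max(np.abs(traj.final_state.density - rho_series)) / rho0 < 1e-3


class TestBoltzmannEquilibrium:
    def test_partition_ratio(self):
        """Reflecting outer wall, beta dG = -2: the stationary interior/
        exterior density ratio is the Boltzmann factor e^2."""
        gel = F.MicrogelSpec(b=10.0, beta_dG=-2.0, R_over_b=3.0)
        grid = F.build_grid(gel)
        mol = probe_molecule(-2.0, 1.0)
        cfg = D.SolverConfig(scheme="implicit", outer_bc="reflecting",
                             f_stop=1.0, t_max=5000.0, include_excess=False)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            traj = D.run_release(gel, mol, grid=grid, config=cfg)
        rho = traj.final_state.density
        assert rho[0] / rho[-1] == pytest.approx(np.exp(2.0), rel=0.01)
        # pointwise Boltzmann profile
        psi = F.effective_potential(grid.centers, gel)
        pred = rho[-1] * np.exp(-psi)
        np.testing.assert_allclose(rho, pred, rtol=0.01)


class TestReleaseObservables:
    def test_half_release_interpolation(self):
        traj = D.ReleaseTrajectory(
            times=np.array([0.0, 10.0, 20.0]), f_rel=np.array([0.0, 0.4, 0.6]),
            N0=1.0, tau0=1.0, complete=False,
        )
        assert D.half_release_time(traj) == pytest.approx(15.0)
        exact = D.ReleaseTrajectory(
            times=np.array([0.0, 7.0]), f_rel=np.array([0.0, 0.5]),
            N0=1.0, tau0=1.0, complete=False,
        )
        assert D.half_release_time(exact) == pytest.approx(7.0)

    def test_half_release_not_reached(self):
        traj = D.ReleaseTrajectory(
            times=np.array([0.0, 1.0]), f_rel=np.array([0.0, 0.2]),
            N0=1.0, tau0=1.0, complete=False,
        )
        with pytest.raises(D.HalfReleaseNotReached):
            D.half_release_time(traj)

    def test_half_release_subsampling_invariance(self):
        traj = quick_release(10.0, -1.0, 0.1, f_stop=0.95)
        th_full = D.half_release_time(traj)
        thin = D.ReleaseTrajectory(
            times=traj.times[::7], f_rel=traj.f_rel[::7],
            N0=traj.N0, tau0=traj.tau0, complete=traj.complete,
        )
        assert D.half_release_time(thin) == pytest.approx(th_full, rel=5e-3)

    def test_mean_release_time_weibull_synthetic(self):
        """tau_bar of a synthetic Weibull curve matches its closed-form mean."""
        from scipy.special import gamma

        chi, nu, tau_half = np.log(2.0), 1.1, 30.0
        t = np.linspace(0.0, 3000.0, 400_000)
        f = 1.0 - np.exp(-chi * (t / tau_half) ** nu)
        traj = D.ReleaseTrajectory(times=t, f_rel=f, N0=1.0, tau0=1.0, complete=True)
        expected = tau_half * gamma(1 + 1 / nu) / chi ** (1 / nu)
        assert D.mean_release_time(traj) == pytest.approx(expected, rel=1e-3)

    def test_mean_release_time_scales_with_time_axis(self):
        traj = quick_release(10.0, -1.0, 0.1, f_stop=0.995)
        tm = D.mean_release_time(traj)
        doubled = D.ReleaseTrajectory(
            times=2 * traj.times, f_rel=traj.f_rel, N0=traj.N0,
            tau0=traj.tau0, complete=traj.complete,
        )
        assert tm > 0
        assert D.mean_release_time(doubled) == pytest.approx(2 * tm, rel=1e-9)

    def test_monotone_release_and_attraction_slows_release(self):
        traj0 = quick_release(10.0, 0.0, 0.1, f_stop=0.95)
        traj_att = quick_release(10.0, -3.0, 0.1, f_stop=0.95)
        assert np.all(np.diff(traj0.f_rel) >= -1e-12)
        assert traj0.f_rel[0] == 0.0
        assert D.half_release_time(traj_att) > D.half_release_time(traj0)


class TestMasterCurveCollapse:
    def test_pairwise_collapse(self, master_trajectories):
        """Release curves of different molecules collapse onto one master
        curve once time is rescaled by tau_1/2 (sup-norm < 0.05), and all
        pass through (1, 0.5)."""
        x_grid = np.linspace(0.05, 5.0, 300)
        rescaled = {}
        for sym, traj in master_trajectories.items():
            th = D.half_release_time(traj)
            rescaled[sym] = np.interp(x_grid, traj.times / th, traj.f_rel)
            assert np.interp(1.0, traj.times / th, traj.f_rel) == pytest.approx(
                0.5, abs=2e-3
            )
        syms = list(rescaled)
        for i in range(len(syms)):
            for j in range(i + 1, len(syms)):
                sup = np.max(np.abs(rescaled[syms[i]] - rescaled[syms[j]]))
                assert sup < 0.05, (syms[i], syms[j], sup)
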