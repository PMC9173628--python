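"""Langevin integrator contracts and the FEP/umbrella-sampling estimators,
checked against the analytic toy systems."""

import numpy as np
import pytest

from evbmech.constants import KB
from evbmech.energy import ground_state_batch
from evbmech.fep import (FreeEnergyProfile, ProfileError, extract_barrier,
                         fep_delta_g, us_profile)
from evbmech.fixtures import make_harmonic_fep_pair, make_marcus_system
from evbmech.sampling import (EVBSystem, IntegrationError, LangevinParams,
                              MappingSchedule, WindowSample, run_langevin,
                              run_mapping)
from evbmech.topology import BondTerm, CouplingTerm, DiabaticState, EVBTopology


@pytest.fixture(scope="module")
def marcus():
    return make_marcus_system(40.0, 0.0, 2.0)


@pytest.fixture(scope="module")
def marcus_windows(marcus):
    # toy systems need near-critical damping (γ ≈ 2ω), not the droplet default
    sched = MappingSchedule(n_windows=55, steps_per_window=8000, sample_stride=4)
    return run_mapping(marcus.system, sched,
                       LangevinParams(300.0, 20.0, 1.0, 0, seed=3))


class TestLangevin:
    def test_nve_energy_conservation(self, marcus):
        traj = run_langevin(marcus.system, LangevinParams(300, 0.0, 1.0, 2000, 1),
                            np.array([1.0, 0.0]), sample_stride=20)
        total = traj.energies + traj.kinetic
        assert total.max() - total.min() < 1e-3

    def test_identical_seeds_identical_trajectories(self, marcus):
        a = run_langevin(marcus.system, LangevinParams(300, 5.0, 1.0, 500, 42),
                         np.array([0.5, 0.5]), sample_stride=10)
        b = run_langevin(marcus.system, LangevinParams(300, 5.0, 1.0, 500, 42),
                         np.array([0.5, 0.5]), sample_stride=10)
        assert np.array_equal(a.final_coords, b.final_coords)
        assert np.array_equal(a.energies, b.energies)

    def test_frozen_atoms_never_move(self, marcus):
        traj = run_langevin(marcus.system, LangevinParams(300, 5.0, 1.0, 300, 2),
                            np.array([0.5, 0.5]))
        assert np.array_equal(traj.final_coords[1:], marcus.system.coordinates[1:])
        # and the frozen y/z of the particle as well
        assert traj.final_coords[0, 1] == marcus.system.coordinates[0, 1]

    def test_equipartition_on_droplet(self, reference_fixture):
        sys = reference_fixture.system
        traj = run_langevin(sys, LangevinParams(300, 10.0, 1.0, 6000, 9),
                            np.array([1.0, 0.0, 0.0]), sample_stride=20)
        ke = traj.kinetic[100:]  # discard relaxation of the built geometry
        n_dof = sys.mobile.sum()
        expect = 0.5 * KB * 300 * n_dof
        # 3-sigma band using block standard error
        blocks = np.array_split(ke, 10)
        se = np.std([b.mean() for b in blocks], ddof=1) / np.sqrt(10)
        assert abs(ke.mean() - expect) < 3 * max(se, 0.01 * expect)

    def test_divergence_reports_step(self):
        # two opposite bare charges placed on top of each other blow up
        states = [DiabaticState(1, [], [], [], np.array([30.0, -30.0]), 0.0),
                  DiabaticState(2, [], [], [], np.array([30.0, -30.0]), 0.0)]
        top = EVBTopology(["A", "B"], ["X", "X"], np.array([1.0, 1.0]),
                          {"X": 0.0}, {"X": 0.0}, states, [CouplingTerm(1, 2, 0.0)])
        sys = EVBSystem(top, np.array([[0.0, 0.0, 0.0], [0.05, 0.0, 0.0]]))
        with pytest.raises(IntegrationError) as err:
            run_langevin(sys, LangevinParams(300, 1.0, 1.0, 2000, 1),
                         np.array([1.0, 0.0]))
        assert err.value.step is not None


class TestMapping:
    def test_window_count_and_endpoints(self, marcus):
        sched = MappingSchedule(n_windows=55, steps_per_window=60, sample_stride=5)
        windows = run_mapping(marcus.system, sched, LangevinParams(300, 10.0, 1.0, 0, 1))
        assert len(windows) == 55
        assert windows[0].lam[0] == pytest.approx(1.0)
        assert windows[-1].lam[1] == pytest.approx(1.0)

    def test_windows_deterministic_in_master_seed(self, marcus):
        sched = MappingSchedule(n_windows=5, steps_per_window=80)
        w1 = run_mapping(marcus.system, sched, LangevinParams(300, 10.0, 1.0, 0, 8))
        w2 = run_mapping(marcus.system, sched, LangevinParams(300, 10.0, 1.0, 0, 8))
        for a, b in zip(w1, w2):
            assert np.array_equal(a.eps, b.eps)


class TestFEPEstimator:
    def test_identical_adjacent_windows_zero_increment(self):
        rng = np.random.default_rng(0)
        eps = np.column_stack([rng.normal(0, 1, 400), rng.normal(5, 1, 400)])
        lam = [np.array([1.0, 0.0]), np.array([1.0, 0.0])]
        wins = [WindowSample(i, lam[i], eps, ground_state_batch(eps, 0.0),
                             eps[:, 0] - eps[:, 1]) for i in range(2)]
        res = fep_delta_g(wins, 300.0)
        assert res.forward == pytest.approx(0.0, abs=1e-9)
        assert res.reverse == pytest.approx(0.0, abs=1e-9)

    def test_harmonic_pair_free_energy(self):
        system, da_exact = make_harmonic_fep_pair(1.0, 4.0, 300.0)
        sched = MappingSchedule(n_windows=31, steps_per_window=12000, sample_stride=6)
        wins = run_mapping(system, sched, LangevinParams(300, 12.0, 1.0, 0, 6))
        res = fep_delta_g(wins, 300.0)
        assert res.delta_g == pytest.approx(da_exact, abs=0.04)

    def test_hysteresis_small_on_toy(self):
        system, _ = make_harmonic_fep_pair(1.0, 4.0, 300.0)
        sched = MappingSchedule(n_windows=21, steps_per_window=6000, sample_stride=6)
        wins = run_mapping(system, sched, LangevinParams(300, 12.0, 1.0, 0, 6))
        assert fep_delta_g(wins, 300.0).hysteresis < 0.1

    def test_too_few_windows(self):
        with pytest.raises(ProfileError):
            fep_delta_g([], 300.0)


class TestUSProfile:
    def test_marcus_barrier_and_reaction_free_energy(self, marcus, marcus_windows):
        profile = us_profile(marcus_windows, 300.0, bin_width=2.0)
        barrier, dg = extract_barrier(profile)
        assert barrier == pytest.approx(marcus.adiabatic_barrier, abs=0.3)
        assert dg == pytest.approx(0.0, abs=0.2)

    def test_profile_zero_at_reactant_minimum(self, marcus_windows):
        profile = us_profile(marcus_windows, 300.0, bin_width=2.0)
        react = profile.bin_centers < 0
        assert profile.dg[react].min() == pytest.approx(0.0, abs=1e-12)

    def test_fep_total_matches_profile_reaction_free_energy(self, marcus_windows):
        profile = us_profile(marcus_windows, 300.0, bin_width=2.0)
        fep = fep_delta_g(marcus_windows, 300.0)
        assert profile.dg_rxn == pytest.approx(fep.delta_g, abs=0.3)

    def test_gauge_invariance_of_extraction(self, marcus_windows):
        profile = us_profile(marcus_windows, 300.0, bin_width=2.0)
        shifted = FreeEnergyProfile(
            bin_centers=profile.bin_centers, dg=profile.dg + 7.3,
            counts=profile.counts, barrier=profile.barrier, dg_rxn=profile.dg_rxn)
        assert extract_barrier(shifted) == extract_barrier(profile)

    def test_single_basin_rejected(self):
        rng = np.random.default_rng(1)
        eps = np.column_stack([rng.normal(0, 1, 200), rng.normal(40, 1, 200)])
        w = WindowSample(0, np.array([1.0, 0.0]), eps,
                         ground_state_batch(eps, 0.0), eps[:, 0] - eps[:, 1])
        with pytest.raises(ProfileError):
            us_profile([w, w], 300.0)

    def test_bootstrap_errors_reported(self, marcus_windows):
        profile = us_profile(marcus_windows, 300.0, bin_width=1.0, n_bootstrap=10,
                             rng=np.random.default_rng(0))
        assert np.isfinite(profile.barrier_se)
        assert profile.barrier_se < 1.0


class TestDetailedBalance:
    def test_boltzmann_populations_match_quadrature(self):
        """Long sampling of the coupled double well reproduces the analytic
        coordinate distribution (binned, 3-sigma per-bin band)."""
        ms = make_marcus_system(10.0, 0.0, 2.0, force_constant=5.0)
        lam = np.array([0.5, 0.5])
        traj = run_langevin(ms.system, LangevinParams(300, 20.0, 1.0, 120000, 17),
                            lam, sample_stride=20, store_coords=True)
        x = traj.coords[300:, 0, 0]
        beta = 1.0 / (KB * 300)
        d = ms.well_separation
        # mapping potential along x (0.5/0.5 mixture of the two diabats)
        grid = np.linspace(x.min() - 0.2, x.max() + 0.2, 2001)
        u = 0.5 * (0.5 * 5.0 * grid ** 2) + 0.5 * (0.5 * 5.0 * (grid - d) ** 2)
        p = np.exp(-beta * (u - u.min()))
        p /= np.trapezoid(p, grid)
        edges = np.linspace(grid[0], grid[-1], 13)
        hist, _ = np.histogram(x, bins=edges, density=True)
        centers = 0.5 * (edges[:-1] + edges[1:])
        p_ref = np.interp(centers, grid, p)
        n = len(x)
        widths = np.diff(edges)
        for h, pr, w in zip(hist, p_ref, widths):
            se = np.sqrt(max(pr * w, 1e-12) / (n / 8)) / w  # ~8x autocorrelation
            assert abs(h - pr) < 3 * se + 0.02
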