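"""Langevin integrator and simulation drivers."""

import numpy as np
import pytest

import saxsbm as sb
from saxsbm.dynamics import (KB_REDUCED, IntegrationError, SimulationConfig,
                             langevin_step, run_simulation)
from saxsbm.forcefield import empty_topology


def _total_energy(traj, n_atoms):
    pot = np.array([e.total for e in traj.energies])
    kin = 1.5 * n_atoms * KB_REDUCED * traj.kinetic_temperature
    return pot + kin


class TestLangevinStep:
    def test_free_flight_without_friction(self):
        cfg = SimulationConfig(temperature=100.0, friction=0.0, dt=0.01,
                               n_steps=1)
        x = np.zeros((2, 3))
        v = np.array([[1.0, 0.0, 0.0], [0.0, -2.0, 0.0]])
        f = np.zeros_like(x)
        rng = np.random.default_rng(0)
        x2, v2, _ = langevin_step(x, v, f, lambda xc: np.zeros_like(xc),
                                  cfg, rng)
        np.testing.assert_allclose(x2, x + 0.01 * v)
        np.testing.assert_allclose(v2, v)

    def test_nonfinite_force_raises(self):
        cfg = SimulationConfig(friction=0.0, dt=0.01)
        x = np.zeros((1, 3))
        v = np.zeros((1, 3))
        with pytest.raises(IntegrationError):
            langevin_step(x, v, np.zeros_like(x),
                          lambda xc: np.full_like(xc, np.nan), cfg,
                          np.random.default_rng(0))


class TestConservation:
    def test_nve_energy_drift_small(self):
        """Zero-friction run of a bonded chain conserves total energy to
        better than 1e-4 relative over 1e5 steps."""
        hairpin, _ = sb.build_two_state_polymer(4, seed=1)
        top = sb.build_topology(hairpin, cutoff=0.7)
        cfg = SimulationConfig(temperature=50.0, friction=0.0, dt=5e-5,
                               n_steps=100_000, output_stride=2000, seed=2)
        traj = run_simulation(hairpin, top, cfg)
        energy = _total_energy(traj, hairpin.n_atoms)
        drift = np.max(np.abs(energy - energy[0])) / abs(energy[0])
        assert drift < 1e-4

    def test_equipartition_ideal_gas(self):
        """Free particles thermostatted at T sample kinetic energy
        k_B T / 2 per degree of freedom (exact for the O-step)."""
        n = 125
        top = empty_topology(n)
        s = sb.Structure(["CA"] * n, ["C"] * n, np.arange(1, n + 1),
                         ["GLY"] * n, ["A"] * n,
                         np.random.default_rng(0).uniform(0, 5, (n, 3)))
        cfg = SimulationConfig(temperature=90.0, friction=5.0, dt=1e-3,
                               n_steps=4000, output_stride=10, seed=4)
        traj = run_simulation(s, top, cfg)
        mean_T = traj.kinetic_temperature[50:].mean()
        n_samples = len(traj.kinetic_temperature) - 50
        se = 90.0 * np.sqrt(2.0 / (3 * n)) / np.sqrt(n_samples / 10)
        assert abs(mean_T - 90.0) < 4 * se

    def test_equipartition_bonded_system(self):
        hairpin, _ = sb.build_two_state_polymer(12, seed=1)
        top = sb.build_topology(hairpin, cutoff=0.7)
        cfg = SimulationConfig(temperature=70.0, friction=2.0, dt=2e-4,
                               n_steps=60_000, output_stride=60, seed=9)
        traj = run_simulation(hairpin, top, cfg)
        mean_T = traj.kinetic_temperature[200:].mean()
        assert mean_T == pytest.approx(70.0, rel=0.15)


class TestRunSimulation:
    def test_zero_steps_single_frame(self, polymer_pair, polymer_topology):
        hairpin, _ = polymer_pair
        cfg = SimulationConfig(n_steps=0, seed=1)
        traj = run_simulation(hairpin, polymer_topology, cfg)
        assert traj.n_frames == 1
        np.testing.assert_array_equal(traj.frames[0], hairpin.coords)

    def test_bitwise_determinism(self, polymer_pair, polymer_topology,
                                 q_grid):
        hairpin, ext = polymer_pair
        diff, ref = sb.make_difference_target(hairpin, ext, q_grid)
        bias = sb.BiasConfig(1e-5, q_grid, diff.I, ref.I)
        cfg = SimulationConfig(temperature=90.0, k_chi=1e-5, n_steps=400,
                               output_stride=40, seed=7)
        a = run_simulation(hairpin, polymer_topology, cfg, bias)
        b = run_simulation(hairpin, polymer_topology, cfg, bias)
        assert np.array_equal(a.frames, b.frames)
        assert np.array_equal(a.v_xs, b.v_xs)

    def test_zero_k_chi_reduces_to_free_sbm(self, polymer_pair,
                                            polymer_topology, q_grid):
        hairpin, ext = polymer_pair
        diff, ref = sb.make_difference_target(hairpin, ext, q_grid)
        bias = sb.BiasConfig(0.0, q_grid, diff.I, ref.I)
        cfg = SimulationConfig(temperature=80.0, k_chi=0.0, n_steps=300,
                               output_stride=50, seed=3)
        free = run_simulation(hairpin, polymer_topology, cfg)
        with_bias_obj = run_simulation(hairpin, polymer_topology, cfg, bias)
        assert np.array_equal(free.frames, with_bias_obj.frames)
        assert np.all(with_bias_obj.v_xs == 0.0)

    def test_frame_count_and_times(self, polymer_pair, polymer_topology):
        hairpin, _ = polymer_pair
        cfg = SimulationConfig(n_steps=1000, output_stride=300, seed=1)
        traj = run_simulation(hairpin, polymer_topology, cfg)
        assert traj.n_frames == 1000 // 300 + 1
        assert np.all(np.diff(traj.times) > 0)

    def test_blow_up_reports_last_stable_frame(self, polymer_pair,
                                               polymer_topology, q_grid):
        hairpin, ext = polymer_pair
        diff, ref = sb.make_difference_target(hairpin, ext, q_grid)
        bias = sb.BiasConfig(1e6, q_grid, diff.I, ref.I)  # absurd coupling
        cfg = SimulationConfig(temperature=90.0, k_chi=1e6, n_steps=5000,
                               output_stride=10, seed=1)
        with pytest.raises(IntegrationError) as err:
            run_simulation(hairpin, polymer_topology, cfg, bias)
        assert err.value.x_last.shape == hairpin.coords.shape
        assert err.value.step > 0


class TestGuidedTransition:
    def test_target_reached_across_seeds(self, polymer_pair,
                                         polymer_topology, q_grid):
        """Clean difference data drive the hairpin onto the extended
        target well below the free-run fluctuation level, and the
        minimum target RMSD does not increase with the bias weight
        over the stable coupling range."""
        hairpin, ext = polymer_pair
        diff, ref = sb.make_difference_target(hairpin, ext, q_grid)

        free_cfg = SimulationConfig(temperature=90.0, n_steps=4000,
                                    output_stride=100, seed=0)
        free = run_simulation(hairpin, polymer_topology, free_cfg)
        free_rmsd = np.array([sb.kabsch_rmsd(f, ext.coords)
                              for f in free.frames])
        free_level = free_rmsd.mean()

        for seed in (1, 2, 3):
            minima = []
            for k_chi in (1e-6, 1e-5):
                cfg = SimulationConfig(temperature=90.0, k_chi=k_chi,
                                       n_steps=8000, output_stride=100,
                                       seed=seed)
                bias = sb.BiasConfig(k_chi, q_grid, diff.I, ref.I)
                traj = run_simulation(hairpin, polymer_topology, cfg, bias)
                rmsd = np.array([sb.kabsch_rmsd(f, ext.coords)
                                 for f in traj.frames])
                minima.append(rmsd.min())
            assert minima[0] < free_level / 2
            assert minima[1] <= minima[0] + 0.02

    def test_guided_chi2_below_free_baseline(self, polymer_pair,
                                             polymer_topology, q_grid):
        hairpin, ext = polymer_pair
        diff, ref = sb.make_difference_target(hairpin, ext, q_grid)
        bias = sb.BiasConfig(1e-5, q_grid, diff.I, ref.I)
        sites = sb.residue_sites(hairpin.coords, hairpin)
        ff = sb.default_form_factors(sites.residue_types, q_grid)
        cfg0 = sb.BiasConfig(1.0, q_grid, diff.I, ref.I)
        baseline = sb.chi2(sb.debye_intensity(sites, ff, q_grid), cfg0)
        cfg = SimulationConfig(temperature=90.0, k_chi=1e-5, n_steps=6000,
                               output_stride=100, seed=2)
        traj = run_simulation(hairpin, polymer_topology, cfg, bias)
        assert traj.chi2[len(traj.chi2) // 2:].mean() < baseline


class TestGridSearch:
    def test_single_cell_matches_direct_run(self, polymer_pair,
                                            polymer_topology, q_grid):
        hairpin, ext = polymer_pair
        diff, ref = sb.make_difference_target(hairpin, ext, q_grid)
        bias = sb.BiasConfig(1.0, q_grid, diff.I, ref.I)
        base = SimulationConfig(n_steps=500, output_stride=100)
        table = sb.grid_search(hairpin, polymer_topology, ext, bias,
                               [90.0], [1e-5], base, seed=42)
        assert len(table) == 1
        cfg = SimulationConfig(temperature=90.0, k_chi=1e-5, n_steps=500,
                               output_stride=100, seed=42)
        direct = run_simulation(hairpin, polymer_topology, cfg,
                                sb.BiasConfig(1e-5, q_grid, diff.I, ref.I))
        rmsd = min(sb.kabsch_rmsd(f, ext.coords) for f in direct.frames)
        assert table.loc[0, "min_target_rmsd"] == pytest.approx(rmsd)
        assert table.loc[0, "v_xs_av"] == pytest.approx(direct.v_xs.mean())

    def test_free_column_zero_bias(self, polymer_pair, polymer_topology,
                                   q_grid):
        hairpin, ext = polymer_pair
        diff, ref = sb.make_difference_target(hairpin, ext, q_grid)
        bias = sb.BiasConfig(1.0, q_grid, diff.I, ref.I)
        base = SimulationConfig(n_steps=300, output_stride=100)
        table = sb.grid_search(hairpin, polymer_topology, ext, bias,
                               [70.0], [0.0], base, seed=1)
        assert table.loc[0, "v_xs_av"] == 0.0

    def test_blow_up_recorded_not_fatal(self, polymer_pair,
                                        polymer_topology, q_grid):
        hairpin, ext = polymer_pair
        diff, ref = sb.make_difference_target(hairpin, ext, q_grid)
        bias = sb.BiasConfig(1.0, q_grid, diff.I, ref.I)
        base = SimulationConfig(n_steps=2000, output_stride=100)
        table = sb.grid_search(hairpin, polymer_topology, ext, bias,
                               [90.0], [1e6, 0.0], base, seed=1)
        assert bool(table.loc[0, "failed"])
        assert np.isnan(table.loc[0, "min_target_rmsd"])
        assert not bool(table.loc[1, "failed"])
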