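"""Langevin dynamics in reduced units driving V = V_SB + V_XS.

All beads have unit mass. Temperature is given in reduced GROMACS-style
units with k_B = 0.00831451 eps per temperature unit, so a reduced
temperature of ~120 corresponds to a thermal energy of ~1 eps (the
folding-temperature regime of structure-based models normalized so that
contact plus dihedral energy equals the atom count).

The integrator is a BAOAB-splitting Langevin leapfrog; with zero
friction the O-step is the identity and the scheme reduces exactly to
velocity Verlet, which is what the energy-conservation checks exercise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bias import BiasConfig, bias_energy_forces
from .forcefield import EnergyBreakdown, SBMTopology, sbm_energy_forces
from .scattering import FormFactorTable, default_form_factors
from .structure import Structure

KB_REDUCED = 0.00831451  # eps per reduced temperature unit


class IntegrationError(RuntimeError):
    """Integrator blow-up; carries the failing step and last stable frame."""

    def __init__(self, step: int, x_last: np.ndarray, message: str = ""):
        super().__init__(message or f"non-finite state at step {step}")
        self.step = step
        self.x_last = x_last


@dataclass
class SimulationConfig:
    temperature: float = 90.0      # reduced GROMACS-style units
    k_chi: float = 0.0             # eps; 0 -> free simulation
    dt: float = 0.0005             # reduced time
    friction: float = 1.0          # inverse reduced time
    n_steps: int = 10000
    output_stride: int = 100
    bias_stride: int = 1           # recompute the bias every n steps
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.n_steps < 0 or self.output_stride < 1 or self.bias_stride < 1:
            raise ValueError("invalid step/stride settings")
        if self.temperature < 0 or self.friction < 0:
            raise ValueError("temperature and friction must be non-negative")


@dataclass
class Trajectory:
    """Time-ordered frames with per-frame energy records."""

    frames: np.ndarray             # (n_frames, n_atoms, 3) nm
    times: np.ndarray              # reduced time
    energies: list[EnergyBreakdown]
    v_xs: np.ndarray               # eps per frame (0 when unbiased)
    chi2: np.ndarray               # per frame (0 when unbiased)
    kinetic_temperature: np.ndarray

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


def maxwell_boltzmann_velocities(n_atoms: int, temperature: float,
                                 rng: np.random.Generator) -> np.ndarray:
    sd = np.sqrt(KB_REDUCED * temperature)
    return sd * rng.standard_normal((n_atoms, 3))


def instantaneous_temperature(v: np.ndarray) -> float:
    """Kinetic temperature from equipartition, 3N degrees of freedom."""
    ke = 0.5 * float(np.sum(v * v))
    return 2.0 * ke / (3.0 * v.shape[0] * KB_REDUCED)


def langevin_step(x: np.ndarray, v: np.ndarray, forces: np.ndarray,
                  force_fn, cfg: SimulationConfig,
                  rng: np.random.Generator):
    """One BAOAB step with unit masses; returns (x', v', forces').

    ``force_fn(x)`` must return the total force at x. With friction 0
    the step is exactly velocity Verlet (free flight for zero force).
    """
    dt = cfg.dt
    v = v + 0.5 * dt * forces
    x = x + 0.5 * dt * v
    if cfg.friction > 0:
        c1 = np.exp(-cfg.friction * dt)
        c2 = np.sqrt((1.0 - c1 * c1) * KB_REDUCED * cfg.temperature)
        v = c1 * v + c2 * rng.standard_normal(v.shape)
    x = x + 0.5 * dt * v
    new_forces = force_fn(x)
    if not np.all(np.isfinite(new_forces)):
        raise IntegrationError(-1, x, "non-finite force")
    v = v + 0.5 * dt * new_forces
    return x, v, new_forces


def run_simulation(s: Structure, top: SBMTopology, cfg: SimulationConfig,
                   bias: BiasConfig | None = None,
                   ff: FormFactorTable | None = None) -> Trajectory:
    """Free or scattering-guided Langevin run started from ``s``.

    Deterministic for a fixed (config, seed) pair. The bias term is
    recomputed every ``cfg.bias_stride`` steps and held constant in
    between; per-frame records include the V_SB breakdown, V_XS and
    chi^2 (both zero for free runs), and the kinetic temperature.
    """
    biased = bias is not None and cfg.k_chi != 0.0
    if biased and ff is None:
        from .scattering import residue_sites
        ff = default_form_factors(
            residue_sites(s.coords, s).residue_types, bias.q)
    if biased and bias.k_chi != cfg.k_chi:
        # the run configuration owns the coupling strength
        bias = BiasConfig(cfg.k_chi, bias.q, bias.delta_I_exp, bias.I_ref,
                          bias.sigma_q, bias.alpha)

    rng = np.random.default_rng(cfg.seed)
    x = s.coords.copy()
    v = maxwell_boltzmann_velocities(s.n_atoms, cfg.temperature, rng)

    state = {"v_xs": 0.0, "chi2": 0.0, "bias_forces": np.zeros_like(x),
             "step": 0}

    def total_force(xc: np.ndarray) -> np.ndarray:
        _, f = sbm_energy_forces(xc, top)
        if biased and state["step"] % cfg.bias_stride == 0:
            v_xs, bf, c2, _ = bias_energy_forces(xc, s, ff, bias)
            state["v_xs"], state["chi2"], state["bias_forces"] = v_xs, c2, bf
        return f + state["bias_forces"] if biased else f

    frames, times, energies = [], [], []
    v_series, c_series, t_series = [], [], []

    def record(step: int, xc: np.ndarray, vc: np.ndarray) -> None:
        e, _ = sbm_energy_forces(xc, top)
        frames.append(xc.copy())
        times.append(step * cfg.dt)
        energies.append(e)
        v_series.append(state["v_xs"] if biased else 0.0)
        c_series.append(state["chi2"] if biased else 0.0)
        t_series.append(instantaneous_temperature(vc))

    forces = total_force(x)
    record(0, x, v)
    for step in range(1, cfg.n_steps + 1):
        state["step"] = step
        try:
            x, v, forces = langevin_step(x, v, forces, total_force, cfg, rng)
        except IntegrationError as exc:
            raise IntegrationError(step, frames[-1],
                                   f"integrator failure at step {step}") from exc
        if not np.all(np.isfinite(x)) or np.max(np.abs(x)) > 1e4:
            raise IntegrationError(step, frames[-1],
                                   f"integrator blow-up at step {step}")
        if step % cfg.output_stride == 0:
            record(step, x, v)

    return Trajectory(np.asarray(frames), np.asarray(times), energies,
                      np.asarray(v_series), np.asarray(c_series),
                      np.asarray(t_series))


def grid_search(s: Structure, top: SBMTopology, target: Structure,
                bias_template: BiasConfig, temperatures, k_chi_values,
                base_cfg: SimulationConfig, reps: int = 1,
                seed: int = 0, ff: FormFactorTable | None = None):
    """Scan (T, k_chi); per cell: min target RMSD, average V_XS, average chi^2.

    Individual blow-ups are recorded as undefined (NaN) cells rather
    than aborting the scan. Returns a pandas DataFrame with one row per
    (temperature, k_chi, rep).
    """
    import pandas as pd

    from .analysis import kabsch_rmsd

    ca_s = s.ca_indices()
    ca_t = target.ca_indices()
    rows = []
    run_id = 0
    for T in temperatures:
        for kx in k_chi_values:
            for rep in range(reps):
                cfg = SimulationConfig(
                    temperature=T, k_chi=kx, dt=base_cfg.dt,
                    friction=base_cfg.friction, n_steps=base_cfg.n_steps,
                    output_stride=base_cfg.output_stride,
                    bias_stride=base_cfg.bias_stride,
                    seed=seed + run_id)
                run_id += 1
                try:
                    traj = run_simulation(s, top, cfg, bias_template, ff=ff)
                    rmsd = np.array([
                        kabsch_rmsd(fr[ca_s], target.coords[ca_t])
                        for fr in traj.frames])
                    rows.append(dict(temperature=T, k_chi=kx, rep=rep,
                                     min_target_rmsd=float(rmsd.min()),
                                     v_xs_av=float(traj.v_xs.mean()),
                                     chi2_av=float(traj.chi2.mean()),
                                     failed=False))
                except IntegrationError:
                    rows.append(dict(temperature=T, k_chi=kx, rep=rep,
                                     min_target_rmsd=np.nan, v_xs_av=np.nan,
                                     chi2_av=np.nan, failed=True))
    return pd.DataFrame(rows)
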