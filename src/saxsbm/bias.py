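"""Scattering bias: difference targets, noise model, sigma weights, V_XS.

The simulation potential is V = V_SB + V_XS with

    V_XS = (k_chi / 2) * chi^2,
    chi^2 = sum_q [ (dI_exp(q) - alpha {I_calc(q) - I_ref(q)}) / sigma_q ]^2

where dI_exp is the (possibly experimental) difference curve, I_ref the
reference intensity of the initial structure, alpha the transition
fraction of the sample (1 when the whole sample converts), and sigma_q
per-point weights built from experimental errors. Difference-curve
errors are preferred over reference-curve errors:

    sigma_q = sigma_D(q)/|dI_exp(q)| + 1   (or sigma_ref/|I_ref| + 1)

so that error-free data give sigma_q = 1 and noisy wide-angle points are
down-weighted. Synthetic noise follows the square-root model: each clean
intensity is blurred with a Gaussian of standard deviation sqrt(I), and
difference errors add as the sum of the two absolute standard deviations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structure import Structure
from .scattering import (FormFactorTable, ScatteringCurve, debye_gradient,
                         debye_intensity, default_form_factors, residue_sites)

SIGMA_GUARD_REL = 1e-6  # guard for zero crossings of the difference curve


class GridMismatchError(ValueError):
    """Curves defined on different q grids."""


def _check_grids(*qs: np.ndarray) -> None:
    q0 = qs[0]
    for q in qs[1:]:
        if q.shape != q0.shape or not np.allclose(q, q0, rtol=0, atol=1e-12):
            raise GridMismatchError("q grids differ")


@dataclass
class BiasConfig:
    """Everything the bias term needs besides the current coordinates."""

    k_chi: float                  # eps; 0 disables the bias
    q: np.ndarray                 # nm^-1
    delta_I_exp: np.ndarray       # target difference intensity per q
    I_ref: np.ndarray             # reference intensity of the initial structure
    sigma_q: np.ndarray | None = None  # defaults to 1 everywhere
    alpha: float = 1.0            # transition fraction in (0, 1]

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=np.float64)
        self.delta_I_exp = np.asarray(self.delta_I_exp, dtype=np.float64)
        self.I_ref = np.asarray(self.I_ref, dtype=np.float64)
        if self.sigma_q is None:
            self.sigma_q = np.ones_like(self.q)
        self.sigma_q = np.asarray(self.sigma_q, dtype=np.float64)
        for arr in (self.delta_I_exp, self.I_ref, self.sigma_q):
            if arr.shape != self.q.shape:
                raise GridMismatchError("curve arrays must share the q grid")
        if np.any(self.sigma_q <= 0):
            raise ValueError("sigma_q must be positive")
        if not (0.0 < self.alpha <= 1.0):
            raise ValueError("alpha must lie in (0, 1]")


def make_difference_target(init: Structure, target: Structure,
                           q: np.ndarray,
                           ff_provider=default_form_factors) -> tuple[ScatteringCurve, ScatteringCurve]:
    """Clean difference target: (dI_exp, I_ref) from two structures.

    dI_exp = I_Debye(target) - I_Debye(init); by construction
    dI_exp + I_ref equals the target's absolute intensity exactly.
    """
    q = np.asarray(q, dtype=np.float64)
    sites_i = residue_sites(init.coords, init)
    sites_t = residue_sites(target.coords, target)
    ff = ff_provider(sites_i.residue_types + sites_t.residue_types, q)
    I_ref = debye_intensity(sites_i, ff, q)
    I_tgt = debye_intensity(sites_t, ff, q)
    return ScatteringCurve(q, I_tgt.I - I_ref.I), I_ref


def add_noise(curve: ScatteringCurve, seed: int) -> ScatteringCurve:
    """Blur a clean curve with Gaussian noise of sd = sqrt(I) per point."""
    if np.any(curve.I < 0):
        raise ValueError("noise model requires non-negative intensities")
    rng = np.random.default_rng(seed)
    sd = np.sqrt(curve.I)
    return ScatteringCurve(curve.q, curve.I + sd * rng.standard_normal(len(curve.q)),
                           err=sd)


def noisy_difference(I_ref_blur: ScatteringCurve,
                     I_tgt_blur: ScatteringCurve) -> tuple[ScatteringCurve, np.ndarray]:
    """Noisy difference curve and its propagated error.

    dI = blurred target - blurred reference; the error is the sum of the
    two Gaussians' absolute standard deviations.
    """
    _check_grids(I_ref_blur.q, I_tgt_blur.q)
    if I_ref_blur.err is None or I_tgt_blur.err is None:
        raise ValueError("blurred curves must carry errors")
    sigma_delta = np.abs(I_ref_blur.err) + np.abs(I_tgt_blur.err)
    return ScatteringCurve(I_ref_blur.q, I_tgt_blur.I - I_ref_blur.I,
                           err=sigma_delta), sigma_delta


def sigma_weights(err: np.ndarray | None, denom_curve: np.ndarray,
                  q: np.ndarray) -> np.ndarray:
    """Per-q weights sigma_q = err/|curve| + 1; all ones without errors.

    ``denom_curve`` is the difference curve when difference errors are
    supplied (preferred) or the reference curve for reference errors.
    """
    q = np.asarray(q, dtype=np.float64)
    if err is None:
        return np.ones_like(q)
    err = np.asarray(err, dtype=np.float64)
    denom_curve = np.asarray(denom_curve, dtype=np.float64)
    if err.shape != q.shape or denom_curve.shape != q.shape:
        raise GridMismatchError("errors and curve must share the q grid")
    if not np.any(err):
        return np.ones_like(q)
    guard = SIGMA_GUARD_REL * np.max(np.abs(denom_curve))
    denom = np.maximum(np.abs(denom_curve), max(guard, 1e-300))
    return err / denom + 1.0


def chi2(I_calc: ScatteringCurve, cfg: BiasConfig) -> float:
    """Weighted squared residual of the current difference signal."""
    _check_grids(I_calc.q, cfg.q)
    resid = (cfg.delta_I_exp - cfg.alpha * (I_calc.I - cfg.I_ref)) / cfg.sigma_q
    return float(np.dot(resid, resid))


def bias_energy_forces(x: np.ndarray, s: Structure, ff: FormFactorTable,
                       cfg: BiasConfig):
    """V_XS = (k_chi/2) chi^2 and its forces on atoms (-gradient).

    Site gradients from the Debye derivative are distributed to each
    residue's atoms with the centre-of-mass weights (chain rule).
    """
    x = np.asarray(x, dtype=np.float64)
    sites = residue_sites(x, s)
    I_calc = debye_intensity(sites, ff, cfg.q)
    resid = (cfg.delta_I_exp - cfg.alpha * (I_calc.I - cfg.I_ref)) / cfg.sigma_q
    v_xs = 0.5 * cfg.k_chi * float(np.dot(resid, resid))

    grad_I = debye_gradient(sites, ff, cfg.q)       # (nq, n_sites, 3)
    # dV/dsite = k_chi * sum_q resid * (-alpha/sigma_q) * dI/dsite
    coef = cfg.k_chi * resid * (-cfg.alpha / cfg.sigma_q)
    site_grad = np.einsum("q,qid->id", coef, grad_I)
    forces = np.zeros_like(x)
    for g, w, sg in zip(sites.atom_groups, sites.weights, site_grad):
        forces[g] -= np.outer(w, sg)
    return v_xs, forces, float(np.dot(resid, resid)), I_calc
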