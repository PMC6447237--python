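"""Trajectory and result metrics: superposition RMSD, shape descriptors,
end-to-end statistics, bias/RMSD correlation, and best-structure extraction.

All RMSDs are computed on CA atoms after optimal rigid superposition
(Kabsch algorithm, proper rotations only). Shape descriptors come from
the gyration tensor: R_g^2 is the trace of its eigenvalues and the
asphericity A = [(l1-l2)^2 + (l2-l3)^2 + (l3-l1)^2] / [2 (l1+l2+l3)^2]
lies in [0, 1], vanishing for spherically symmetric mass distributions
and reaching 1 for a collinear rod.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .structure import Structure
from .dynamics import Trajectory


def kabsch_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Minimal RMSD of two matched point sets over rigid superposition.

    Proper rotations only (reflections are excluded by flipping the sign
    of the smallest singular vector when det < 0).
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 2 or a.shape[0] < 3:
        raise ValueError("need two matching (n>=3, 3) coordinate sets")
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    h = ac.T @ bc
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    resid = ac @ rot.T - bc
    return math.sqrt(float(np.sum(resid * resid)) / a.shape[0])


def end_to_end(x: np.ndarray, s: Structure) -> float:
    """Distance between the N-terminal and C-terminal CA atoms (nm)."""
    ca = s.ca_indices()
    if len(ca) < 2:
        raise ValueError("need at least two residues")
    x = np.asarray(x, dtype=np.float64)
    return float(np.linalg.norm(x[ca[-1]] - x[ca[0]]))


def _gyration_eigenvalues(x: np.ndarray, masses: np.ndarray | None):
    x = np.asarray(x, dtype=np.float64)
    m = np.ones(x.shape[0]) if masses is None else np.asarray(masses, float)
    w = m / m.sum()
    centred = x - w @ x
    tensor = (centred * w[:, None]).T @ centred
    return np.sort(np.linalg.eigvalsh(tensor))[::-1]


def radius_of_gyration(x: np.ndarray, masses: np.ndarray | None = None) -> float:
    lam = _gyration_eigenvalues(x, masses)
    return math.sqrt(float(np.sum(lam)))


def asphericity(x: np.ndarray, masses: np.ndarray | None = None) -> float:
    if np.asarray(x).shape[0] < 2:
        raise ValueError("asphericity undefined for a single point")
    l1, l2, l3 = _gyration_eigenvalues(x, masses)
    tr = l1 + l2 + l3
    if tr <= 0:
        raise ValueError("degenerate (zero-size) configuration")
    return float(((l1 - l2) ** 2 + (l2 - l3) ** 2 + (l3 - l1) ** 2)
                 / (2.0 * tr * tr))


def pearson(u: np.ndarray, v: np.ndarray) -> float:
    """Sample Pearson correlation coefficient."""
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    if u.shape != v.shape or u.ndim != 1 or len(u) < 2:
        raise ValueError("need two equal-length series of length >= 2")
    du = u - u.mean()
    dv = v - v.mean()
    denom = math.sqrt(float(np.dot(du, du) * np.dot(dv, dv)))
    if denom == 0.0:
        raise ValueError("Pearson correlation undefined for constant series")
    return float(np.dot(du, dv) / denom)


def tau_to_target(rmsd_series: np.ndarray, times: np.ndarray,
                  threshold: float = 0.2) -> float | None:
    """Earliest simulated time with target RMSD below threshold, else None."""
    rmsd_series = np.asarray(rmsd_series, dtype=np.float64)
    times = np.asarray(times, dtype=np.float64)
    hits = np.flatnonzero(rmsd_series < threshold)
    return float(times[hits[0]]) if len(hits) else None


def shared_ca_indices(a: Structure, b: Structure) -> tuple[np.ndarray, np.ndarray]:
    """CA atom indices of the residues the two structures share.

    Matching is by (chain, residue number), so structures that differ in
    coverage (e.g. crystal forms resolving different termini) compare on
    their common residues only.
    """
    keys_a = {k: i for i, k in enumerate(a.residue_keys())}
    keys_b = {k: i for i, k in enumerate(b.residue_keys())}
    shared = [k for k in keys_a if k in keys_b]
    ca_a, ca_b = a.ca_indices(), b.ca_indices()
    return (np.array([ca_a[keys_a[k]] for k in shared]),
            np.array([ca_b[keys_b[k]] for k in shared]))


@dataclass
class AnalysisReport:
    times: np.ndarray
    rmsd_target: np.ndarray
    rmsd_initial: np.ndarray
    rmsd_target_min: float
    rmsd_target_min_frame: int
    v_xs_min: float
    v_xs_min_frame: int
    v_xs_av: float
    chi2_av: float
    pearson_rho: float | None       # None for free runs
    tau_02: float | None            # reduced time, None if never reached
    rmsd_target_at_vxs_min: float
    rmsd_between_best: float        # RMSD(min-RMSD frame, min-V_XS frame)
    rg: np.ndarray
    asphericity: np.ndarray
    end_to_end: np.ndarray

    def to_dict(self) -> dict:
        return {
            "rmsd_target_min": self.rmsd_target_min,
            "rmsd_target_min_frame": self.rmsd_target_min_frame,
            "v_xs_min": self.v_xs_min,
            "v_xs_min_frame": self.v_xs_min_frame,
            "v_xs_av": self.v_xs_av,
            "chi2_av": self.chi2_av,
            "pearson_rho": self.pearson_rho,
            "tau_02": self.tau_02,
            "rmsd_target_at_vxs_min": self.rmsd_target_at_vxs_min,
            "rmsd_between_best": self.rmsd_between_best,
        }


def summarize(traj: Trajectory, initial: Structure, target: Structure,
              threshold: float = 0.2, burn_in: int = 0) -> AnalysisReport:
    """Full per-trajectory report (series, minima, averages, correlation).

    ``burn_in`` frames can be dropped from the V_XS / chi^2 averages;
    the default keeps the whole trajectory.
    """
    if traj.n_frames == 0:
        raise ValueError("empty trajectory")
    ca_i = initial.ca_indices()
    ca_t = target.ca_indices()
    ca_traj = ca_i  # trajectory frames share the initial structure's atoms

    rmsd_t = np.array([kabsch_rmsd(fr[ca_traj], target.coords[ca_t])
                       for fr in traj.frames])
    rmsd_i = np.array([kabsch_rmsd(fr[ca_traj], initial.coords[ca_i])
                       for fr in traj.frames])
    rg = np.array([radius_of_gyration(fr[ca_traj]) for fr in traj.frames])
    asph = np.array([asphericity(fr[ca_traj]) for fr in traj.frames])
    e2e = np.array([end_to_end(fr, initial) for fr in traj.frames])

    k_min = int(np.argmin(rmsd_t))
    v_min = int(np.argmin(traj.v_xs))
    avg_slice = slice(burn_in, None)
    biased = bool(np.any(traj.v_xs != 0))
    rho = None
    if biased:
        try:
            rho = pearson(traj.v_xs, rmsd_t)
        except ValueError:
            rho = None

    ca_sel = initial.ca_indices()
    between = kabsch_rmsd(traj.frames[k_min][ca_sel], traj.frames[v_min][ca_sel])
    return AnalysisReport(
        times=traj.times,
        rmsd_target=rmsd_t,
        rmsd_initial=rmsd_i,
        rmsd_target_min=float(rmsd_t[k_min]),
        rmsd_target_min_frame=k_min,
        v_xs_min=float(traj.v_xs[v_min]),
        v_xs_min_frame=v_min,
        v_xs_av=float(traj.v_xs[avg_slice].mean()),
        chi2_av=float(traj.chi2[avg_slice].mean()),
        pearson_rho=rho,
        tau_02=tau_to_target(rmsd_t, traj.times, threshold),
        rmsd_target_at_vxs_min=float(rmsd_t[v_min]),
        rmsd_between_best=float(between),
        rg=rg,
        asphericity=asph,
        end_to_end=e2e,
    )
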