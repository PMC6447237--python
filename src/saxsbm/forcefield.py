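"""All-atom structure-based (Go-type) force field.

The native structure defines every reference value of the potential:

    V_SB = sum_bonds    K_b (r - r0)^2
         + sum_angles   K_a (theta - theta0)^2
         + sum_improper K_i (chi - chi0)^2
         + sum_propers  K_d [(1 - cos(phi - phi0)) + 1/2 (1 - cos 3(phi - phi0))]
         + sum_contacts K_c [(s0/r)^12 - 2 (s0/r)^6]
         + sum_nonnat   K_nc (s~/r)^12

with no extra 1/2 factors on the harmonic terms. Native contacts are
heavy-atom pairs within a cutoff between residues separated by more than
three sequence positions; all other non-local pairs are purely repulsive.
The uniform contact weight K_c and proper-dihedral weight K_d are scaled
so that the summed contact and dihedral weights equal the number of atoms,
split 2:1 between contacts and dihedrals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structure import Structure
from . import residues as rd

# Energetic weights in reduced units (epsilon).
K_BOND = 20000.0        # eps/nm^2
K_ANGLE = 40.0          # eps/rad^2 (see note on the per-degree reading)
K_IMPROPER = 40.0       # eps/rad^2
K_NONNATIVE = 0.01      # eps
SIGMA_NONNATIVE = 0.25  # nm, excluded-volume radius for Pauli repulsion
CONTACT_CUTOFF = 0.45   # nm, heavy-atom contact map cutoff
CONTACT_DIHEDRAL_RATIO = 2.0
MIN_SEQ_SEPARATION = 3  # contacts require residue separation > 3
PEPTIDE_BREAK_NM = 0.20  # C-N bond beyond this means a chain break
BEAD_BREAK_NM = 0.60


class ChainBreakError(ValueError):
    """Consecutive residues too far apart to be covalently bonded."""


class SingularityError(FloatingPointError):
    """Overlapping atoms in a repulsive pair."""


@dataclass
class EnergyBreakdown:
    bond: float = 0.0
    angle: float = 0.0
    improper: float = 0.0
    proper: float = 0.0
    contact: float = 0.0
    nonnative: float = 0.0

    @property
    def total(self) -> float:
        return (self.bond + self.angle + self.improper + self.proper
                + self.contact + self.nonnative)


@dataclass
class SBMTopology:
    """Interaction lists with native reference values and weights."""

    n_atoms: int
    bonds: np.ndarray        # (nb, 2) int
    bond_r0: np.ndarray      # nm
    bond_k: np.ndarray       # eps/nm^2
    angles: np.ndarray       # (na, 3) int
    angle_t0: np.ndarray     # rad
    angle_k: np.ndarray      # eps/rad^2
    impropers: np.ndarray    # (ni, 4) int
    improper_x0: np.ndarray  # rad
    improper_k: np.ndarray   # eps/rad^2
    propers: np.ndarray      # (nd, 4) int
    proper_p0: np.ndarray    # rad
    proper_k: np.ndarray     # eps
    contacts: np.ndarray     # (nc, 2) int
    contact_sigma: np.ndarray  # nm
    contact_k: np.ndarray      # eps
    nonnative_pairs: np.ndarray  # (nn, 2) int, all repulsive-only pairs
    nonnative_sigma: float = SIGMA_NONNATIVE
    k_nonnative: float = K_NONNATIVE
    exclusions: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        for name in ("bonds", "angles", "impropers", "propers",
                     "contacts", "nonnative_pairs"):
            arr = np.asarray(getattr(self, name), dtype=np.int64)
            width = {"bonds": 2, "angles": 3, "impropers": 4, "propers": 4,
                     "contacts": 2, "nonnative_pairs": 2}[name]
            setattr(self, name, arr.reshape(-1, width))


# ---------------------------------------------------------------------------
# Topology construction
# ---------------------------------------------------------------------------

def _is_bead_chain(s: Structure) -> bool:
    return all(n == "CA" for n in s.atom_names)


def covalent_bonds(s: Structure) -> list[tuple[int, int]]:
    """Bond list from amino-acid templates plus peptide bonds.

    Single-CA pseudo-residues are treated as a bead chain bonded
    consecutively. Chain breaks raise :class:`ChainBreakError`.
    """
    groups = s.residue_groups()
    keys = s.residue_keys()
    bonds: list[tuple[int, int]] = []
    if _is_bead_chain(s):
        for r in range(len(groups) - 1):
            if keys[r][0] != keys[r + 1][0]:
                continue
            i, j = int(groups[r][0]), int(groups[r + 1][0])
            d = np.linalg.norm(s.coords[i] - s.coords[j])
            if d > BEAD_BREAK_NM:
                raise ChainBreakError(
                    f"bead chain break between residues {keys[r]} and {keys[r+1]}"
                    f" (distance {d:.3f} nm)")
            bonds.append((i, j))
        return bonds

    for r, g in enumerate(groups):
        res = s.res_names[g[0]]
        name_to_idx = {s.atom_names[a]: int(a) for a in g}
        for a1, a2 in rd.residue_bonds(res):
            if a1 in name_to_idx and a2 in name_to_idx:
                bonds.append((name_to_idx[a1], name_to_idx[a2]))
        if "OXT" in name_to_idx and "C" in name_to_idx:
            bonds.append((name_to_idx["C"], name_to_idx["OXT"]))
        if r + 1 < len(groups) and keys[r][0] == keys[r + 1][0]:
            nxt = groups[r + 1]
            nxt_names = {s.atom_names[a]: int(a) for a in nxt}
            if "C" in name_to_idx and "N" in nxt_names:
                ci, ni = name_to_idx["C"], nxt_names["N"]
                d = np.linalg.norm(s.coords[ci] - s.coords[ni])
                if d > PEPTIDE_BREAK_NM:
                    raise ChainBreakError(
                        f"chain break between residues {keys[r]} and "
                        f"{keys[r+1]} (C-N distance {d:.3f} nm)")
                bonds.append((ci, ni))
    return bonds


def build_contacts(s: Structure, cutoff: float = CONTACT_CUTOFF) -> list[tuple[int, int, float]]:
    """Native contact pairs (i, j, sigma0) from a heavy-atom cutoff map.

    A pair of atoms is a contact when their native distance is at most
    ``cutoff`` and their residues sit more than three sequence positions
    apart (residues on different chains always qualify).
    """
    groups = s.residue_groups()
    keys = s.residue_keys()
    atom_res = np.empty(s.n_atoms, dtype=np.int64)
    atom_chain = np.empty(s.n_atoms, dtype=object)
    for r, g in enumerate(groups):
        atom_res[g] = r
        atom_chain[g] = keys[r][0]
    d = np.linalg.norm(s.coords[:, None, :] - s.coords[None, :, :], axis=-1)
    ii, jj = np.triu_indices(s.n_atoms, k=1)
    near = d[ii, jj] <= cutoff
    contacts = []
    for i, j in zip(ii[near], jj[near]):
        ri, rj = atom_res[i], atom_res[j]
        same_chain = atom_chain[i] == atom_chain[j]
        if same_chain and abs(int(ri) - int(rj)) <= MIN_SEQ_SEPARATION:
            continue
        contacts.append((int(i), int(j), float(d[i, j])))
    return contacts


def _graph_distances_leq(bonds: list[tuple[int, int]], n_atoms: int,
                         max_dist: int) -> set[frozenset]:
    adj: dict[int, set[int]] = {i: set() for i in range(n_atoms)}
    for i, j in bonds:
        adj[i].add(j)
        adj[j].add(i)
    close: set[frozenset] = set()
    for start in range(n_atoms):
        frontier = {start}
        seen = {start}
        for _ in range(max_dist):
            nxt = set()
            for u in frontier:
                nxt |= adj[u]
            nxt -= seen
            for v in nxt:
                close.add(frozenset((start, v)))
            seen |= nxt
            frontier = nxt
    return close


def _bond_in_ring(adj: dict[int, set[int]], i: int, j: int) -> bool:
    stack, seen = [i], {i}
    while stack:
        cur = stack.pop()
        if cur == j:
            return True
        for nxt in adj[cur]:
            if (cur, nxt) in ((i, j), (j, i)) or nxt in seen:
                continue
            seen.add(nxt)
            stack.append(nxt)
    return False


def _angle(x: np.ndarray, i: int, j: int, k: int) -> float:
    u = x[i] - x[j]
    v = x[k] - x[j]
    c = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.arccos(np.clip(c, -1.0, 1.0)))


def _dihedral(x: np.ndarray, i: int, j: int, k: int, l: int) -> float:
    b1 = x[j] - x[i]
    b2 = x[k] - x[j]
    b3 = x[l] - x[k]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m = np.cross(n1, b2 / np.linalg.norm(b2))
    return float(np.arctan2(np.dot(m, n2), np.dot(n1, n2)))


def _dihedral_defined(x: np.ndarray, i: int, j: int, k: int, l: int,
                      tol: float = 1e-3) -> bool:
    b1 = x[j] - x[i]
    b2 = x[k] - x[j]
    b3 = x[l] - x[k]
    n1 = np.linalg.norm(np.cross(b1, b2))
    n2 = np.linalg.norm(np.cross(b2, b3))
    scale = np.linalg.norm(b2)
    return n1 > tol * scale * max(np.linalg.norm(b1), 1e-12) and \
        n2 > tol * scale * max(np.linalg.norm(b3), 1e-12)


def build_topology(s: Structure, cutoff: float = CONTACT_CUTOFF,
                   contact_dihedral_ratio: float = CONTACT_DIHEDRAL_RATIO,
                   k_angle: float = K_ANGLE, k_improper: float = K_IMPROPER,
                   angle_units: str = "rad") -> SBMTopology:
    """Build the full SBM interaction topology from a native structure.

    Bonds come from covalent connectivity, angles from all bonded
    triplets, one proper dihedral per rotatable (non-ring) central bond,
    impropers at every centre with three or more heavy neighbours
    (sp2 planarity and CA chirality), and contacts from the cutoff map.
    The uniform weights K_c and K_d are normalized so that
    sum(K_c) + sum(K_d) = n_atoms with a contact:dihedral split of
    ``contact_dihedral_ratio`` : 1.

    ``angle_units='deg'`` applies the harmonic angle/improper constants
    per squared degree instead of per squared radian.
    """
    x = s.coords
    n = s.n_atoms
    bonds = covalent_bonds(s)
    adj: dict[int, set[int]] = {i: set() for i in range(n)}
    for i, j in bonds:
        adj[i].add(j)
        adj[j].add(i)

    angles = []
    for j in range(n):
        nbrs = sorted(adj[j])
        for a in range(len(nbrs)):
            for b in range(a + 1, len(nbrs)):
                angles.append((nbrs[a], j, nbrs[b]))

    propers = []
    for (j, k) in bonds:
        others_j = sorted(adj[j] - {k})
        others_k = sorted(adj[k] - {j})
        if not others_j or not others_k:
            continue
        if _bond_in_ring(adj, j, k):
            continue
        i, l = others_j[0], others_k[0]
        if _dihedral_defined(x, i, j, k, l):
            propers.append((i, j, k, l))

    impropers = []
    for c in range(n):
        nbrs = sorted(adj[c])
        if len(nbrs) >= 3:
            i, j, k = nbrs[:3]
            if _dihedral_defined(x, i, j, c, k):
                impropers.append((i, j, c, k))

    contact_list = build_contacts(s, cutoff)
    n_contacts = len(contact_list)
    n_propers = len(propers)

    r = contact_dihedral_ratio
    if n_contacts and n_propers:
        sum_kc = n * r / (1.0 + r)
        sum_kd = n / (1.0 + r)
    elif n_contacts:
        sum_kc, sum_kd = float(n), 0.0
    elif n_propers:
        sum_kc, sum_kd = 0.0, float(n)
    else:
        sum_kc = sum_kd = 0.0
    kc = sum_kc / n_contacts if n_contacts else 0.0
    kd = sum_kd / n_propers if n_propers else 0.0

    ang_scale = 1.0 if angle_units == "rad" else (180.0 / np.pi) ** 2

    bond_arr = np.asarray(bonds, dtype=np.int64).reshape(-1, 2)
    bond_r0 = np.linalg.norm(x[bond_arr[:, 0]] - x[bond_arr[:, 1]], axis=1) \
        if len(bonds) else np.empty(0)
    angle_arr = np.asarray(angles, dtype=np.int64).reshape(-1, 3)
    angle_t0 = np.array([_angle(x, *a) for a in angles])
    imp_arr = np.asarray(impropers, dtype=np.int64).reshape(-1, 4)
    imp_x0 = np.array([_dihedral(x, *d) for d in impropers])
    prop_arr = np.asarray(propers, dtype=np.int64).reshape(-1, 4)
    prop_p0 = np.array([_dihedral(x, *d) for d in propers])
    cont_arr = np.asarray([(i, j) for i, j, _ in contact_list],
                          dtype=np.int64).reshape(-1, 2)
    cont_sigma = np.asarray([sig for _, _, sig in contact_list])

    close = _graph_distances_leq(bonds, n, 3)
    exclusions = close | {frozenset((int(i), int(j))) for i, j, _ in contact_list}
    ii, jj = np.triu_indices(n, k=1)
    mask = np.array([frozenset((int(a), int(b))) not in exclusions
                     for a, b in zip(ii, jj)])
    nonnative = np.stack([ii[mask], jj[mask]], axis=1) if n > 1 else \
        np.empty((0, 2), dtype=np.int64)

    return SBMTopology(
        n_atoms=n,
        bonds=bond_arr, bond_r0=bond_r0,
        bond_k=np.full(len(bonds), K_BOND),
        angles=angle_arr, angle_t0=angle_t0,
        angle_k=np.full(len(angles), k_angle * ang_scale),
        impropers=imp_arr, improper_x0=imp_x0,
        improper_k=np.full(len(impropers), k_improper * ang_scale),
        propers=prop_arr, proper_p0=prop_p0,
        proper_k=np.full(len(propers), kd),
        contacts=cont_arr, contact_sigma=cont_sigma,
        contact_k=np.full(n_contacts, kc),
        nonnative_pairs=nonnative,
        exclusions=frozenset(exclusions),
    )


def empty_topology(n_atoms: int) -> SBMTopology:
    """Interaction-free topology of ``n_atoms`` beads (ideal-gas system)."""
    z = np.empty(0)
    return SBMTopology(
        n_atoms=n_atoms,
        bonds=np.empty((0, 2), np.int64), bond_r0=z, bond_k=z,
        angles=np.empty((0, 3), np.int64), angle_t0=z, angle_k=z,
        impropers=np.empty((0, 4), np.int64), improper_x0=z, improper_k=z,
        propers=np.empty((0, 4), np.int64), proper_p0=z, proper_k=z,
        contacts=np.empty((0, 2), np.int64), contact_sigma=z, contact_k=z,
        nonnative_pairs=np.empty((0, 2), np.int64),
        exclusions=frozenset(frozenset((int(i), int(j)))
                             for i in range(n_atoms) for j in range(i)),
    )


# ---------------------------------------------------------------------------
# Energies and analytic forces
# ---------------------------------------------------------------------------

def _accumulate(forces: np.ndarray, idx: np.ndarray, contrib: np.ndarray) -> None:
    np.add.at(forces, idx, contrib)


def _angle_geometry(x: np.ndarray, a: np.ndarray):
    """Angles and gradients d(theta)/dx for (m, 3) index triplets."""
    xi, xj, xk = x[a[:, 0]], x[a[:, 1]], x[a[:, 2]]
    u = xi - xj
    v = xk - xj
    nu = np.linalg.norm(u, axis=1)
    nv = np.linalg.norm(v, axis=1)
    uh = u / nu[:, None]
    vh = v / nv[:, None]
    c = np.clip(np.sum(uh * vh, axis=1), -1.0, 1.0)
    theta = np.arccos(c)
    s = np.sqrt(np.maximum(1.0 - c * c, 1e-16))
    dti = (c[:, None] * uh - vh) / (nu * s)[:, None]
    dtk = (c[:, None] * vh - uh) / (nv * s)[:, None]
    dtj = -(dti + dtk)
    return theta, dti, dtj, dtk


def _dihedral_geometry(x: np.ndarray, d: np.ndarray):
    """Dihedrals and gradients d(phi)/dx for (m, 4) index quadruplets."""
    x1, x2, x3, x4 = x[d[:, 0]], x[d[:, 1]], x[d[:, 2]], x[d[:, 3]]
    b1 = x2 - x1
    b2 = x3 - x2
    b3 = x4 - x3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2, axis=1)
    m = np.cross(n1, b2 / nb2[:, None])
    phi = np.arctan2(np.sum(m * n2, axis=1), np.sum(n1 * n2, axis=1))
    sq1 = np.maximum(np.sum(n1 * n1, axis=1), 1e-16)
    sq2 = np.maximum(np.sum(n2 * n2, axis=1), 1e-16)
    dp1 = (nb2 / sq1)[:, None] * n1
    dp4 = -(nb2 / sq2)[:, None] * n2
    f12 = np.sum(b1 * b2, axis=1) / (nb2 * nb2)
    f32 = np.sum(b3 * b2, axis=1) / (nb2 * nb2)
    dp2 = -(1.0 + f12)[:, None] * dp1 + f32[:, None] * dp4
    dp3 = f12[:, None] * dp1 - (1.0 + f32)[:, None] * dp4
    return phi, dp1, dp2, dp3, dp4


def _wrap_angle(a: np.ndarray) -> np.ndarray:
    return (a + np.pi) % (2.0 * np.pi) - np.pi


def sbm_energy_forces(x: np.ndarray, top: SBMTopology):
    """Evaluate V_SB term by term with analytic forces (-gradient)."""
    x = np.asarray(x, dtype=np.float64)
    if x.shape != (top.n_atoms, 3):
        raise ValueError("coordinate shape does not match topology")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite coordinates")
    e = EnergyBreakdown()
    forces = np.zeros_like(x)

    if len(top.bonds):
        b = top.bonds
        dvec = x[b[:, 0]] - x[b[:, 1]]
        r = np.linalg.norm(dvec, axis=1)
        dr = r - top.bond_r0
        e.bond = float(np.sum(top.bond_k * dr * dr))
        dEdr = 2.0 * top.bond_k * dr
        g = (dEdr / r)[:, None] * dvec
        _accumulate(forces, b[:, 0], -g)
        _accumulate(forces, b[:, 1], g)

    if len(top.angles):
        a = top.angles
        theta, dti, dtj, dtk = _angle_geometry(x, a)
        dt = theta - top.angle_t0
        e.angle = float(np.sum(top.angle_k * dt * dt))
        dEdt = 2.0 * top.angle_k * dt
        _accumulate(forces, a[:, 0], -dEdt[:, None] * dti)
        _accumulate(forces, a[:, 1], -dEdt[:, None] * dtj)
        _accumulate(forces, a[:, 2], -dEdt[:, None] * dtk)

    if len(top.impropers):
        d = top.impropers
        chi, dp1, dp2, dp3, dp4 = _dihedral_geometry(x, d)
        dchi = _wrap_angle(chi - top.improper_x0)
        e.improper = float(np.sum(top.improper_k * dchi * dchi))
        dEdc = 2.0 * top.improper_k * dchi
        for col, dp in enumerate((dp1, dp2, dp3, dp4)):
            _accumulate(forces, d[:, col], -dEdc[:, None] * dp)

    if len(top.propers):
        d = top.propers
        phi, dp1, dp2, dp3, dp4 = _dihedral_geometry(x, d)
        dphi = phi - top.proper_p0
        e.proper = float(np.sum(top.proper_k * (
            (1.0 - np.cos(dphi)) + 0.5 * (1.0 - np.cos(3.0 * dphi)))))
        dEdp = top.proper_k * (np.sin(dphi) + 1.5 * np.sin(3.0 * dphi))
        for col, dp in enumerate((dp1, dp2, dp3, dp4)):
            _accumulate(forces, d[:, col], -dEdp[:, None] * dp)

    if len(top.contacts):
        c = top.contacts
        dvec = x[c[:, 0]] - x[c[:, 1]]
        r = np.linalg.norm(dvec, axis=1)
        if np.any(r < 1e-9):
            raise SingularityError("coincident atoms in a contact pair")
        sr6 = (top.contact_sigma / r) ** 6
        e.contact = float(np.sum(top.contact_k * (sr6 * sr6 - 2.0 * sr6)))
        dEdr = top.contact_k * (-12.0 / r) * (sr6 * sr6 - sr6)
        g = (dEdr / r)[:, None] * dvec
        _accumulate(forces, c[:, 0], -g)
        _accumulate(forces, c[:, 1], g)

    if len(top.nonnative_pairs):
        p = top.nonnative_pairs
        dvec = x[p[:, 0]] - x[p[:, 1]]
        r = np.linalg.norm(dvec, axis=1)
        if np.any(r < 1e-9):
            raise SingularityError("coincident atoms in a repulsive pair")
        sr12 = (top.nonnative_sigma / r) ** 12
        e.nonnative = float(top.k_nonnative * np.sum(sr12))
        dEdr = top.k_nonnative * (-12.0 / r) * sr12
        g = (dEdr / r)[:, None] * dvec
        _accumulate(forces, p[:, 0], -g)
        _accumulate(forces, p[:, 1], g)

    return e, forces


# ---------------------------------------------------------------------------
# Plain-text topology serialization
# ---------------------------------------------------------------------------

def topology_to_text(top: SBMTopology) -> str:
    """Serialize a topology to a documented plain-text format."""
    out = [f"[atoms] {top.n_atoms}",
           f"[nonnative] sigma={float(top.nonnative_sigma)!r} k={float(top.k_nonnative)!r}"]
    out.append("[bonds]")
    for (i, j), r0, k in zip(top.bonds, top.bond_r0, top.bond_k):
        out.append(f"{i} {j} {float(r0)!r} {float(k)!r}")
    out.append("[angles]")
    for (i, j, k_), t0, kk in zip(top.angles, top.angle_t0, top.angle_k):
        out.append(f"{i} {j} {k_} {float(t0)!r} {float(kk)!r}")
    out.append("[impropers]")
    for (i, j, k_, l), x0, kk in zip(top.impropers, top.improper_x0, top.improper_k):
        out.append(f"{i} {j} {k_} {l} {float(x0)!r} {float(kk)!r}")
    out.append("[dihedrals]")
    for (i, j, k_, l), p0, kk in zip(top.propers, top.proper_p0, top.proper_k):
        out.append(f"{i} {j} {k_} {l} {float(p0)!r} {float(kk)!r}")
    out.append("[contacts]")
    for (i, j), sig, kk in zip(top.contacts, top.contact_sigma, top.contact_k):
        out.append(f"{i} {j} {float(sig)!r} {float(kk)!r}")
    out.append("[exclusions]")
    for pair in sorted(tuple(sorted(p)) for p in top.exclusions):
        out.append(f"{pair[0]} {pair[1]}")
    return "\n".join(out) + "\n"


def topology_from_text(text: str) -> SBMTopology:
    """Parse the plain-text topology format written by :func:`topology_to_text`."""
    section = None
    n_atoms = 0
    nn_sigma, nn_k = SIGMA_NONNATIVE, K_NONNATIVE
    data: dict[str, list] = {k: [] for k in
                             ("bonds", "angles", "impropers", "dihedrals",
                              "contacts", "exclusions")}
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("[atoms]"):
            n_atoms = int(line.split()[1])
            section = None
        elif line.startswith("[nonnative]"):
            parts = dict(p.split("=") for p in line.split()[1:])
            nn_sigma, nn_k = float(parts["sigma"]), float(parts["k"])
            section = None
        elif line.startswith("["):
            section = line.strip("[]")
        elif section:
            data[section].append(line.split())

    def ints(rows, n):
        return np.asarray([[int(v) for v in r[:n]] for r in rows],
                          dtype=np.int64).reshape(-1, n)

    def floats(rows, col):
        return np.asarray([float(r[col]) for r in rows])

    bonds, angles = data["bonds"], data["angles"]
    imps, dihs, conts = data["impropers"], data["dihedrals"], data["contacts"]
    exclusions = frozenset(frozenset((int(r[0]), int(r[1])))
                           for r in data["exclusions"])
    ii, jj = np.triu_indices(n_atoms, k=1)
    mask = np.array([frozenset((int(a), int(b))) not in exclusions
                     for a, b in zip(ii, jj)]) if n_atoms > 1 else np.empty(0, bool)
    nonnative = np.stack([ii[mask], jj[mask]], axis=1) if n_atoms > 1 else \
        np.empty((0, 2), dtype=np.int64)
    return SBMTopology(
        n_atoms=n_atoms,
        bonds=ints(bonds, 2), bond_r0=floats(bonds, 2), bond_k=floats(bonds, 3),
        angles=ints(angles, 3), angle_t0=floats(angles, 3),
        angle_k=floats(angles, 4),
        impropers=ints(imps, 4), improper_x0=floats(imps, 4),
        improper_k=floats(imps, 5),
        propers=ints(dihs, 4), proper_p0=floats(dihs, 4), proper_k=floats(dihs, 5),
        contacts=ints(conts, 2), contact_sigma=floats(conts, 2),
        contact_k=floats(conts, 3),
        nonnative_pairs=nonnative, nonnative_sigma=nn_sigma, k_nonnative=nn_k,
        exclusions=exclusions,
    )
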