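"""Protein structures: PDB I/O, normalization, and synthetic fixture builders.

Coordinates are stored in nanometres throughout the package; the PDB
Angstrom scale is converted on read and write. Structures are normalized
for structure-based model construction: heavy atoms only, one altloc per
atom, no HETATM/water records.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import residues as rd

A_PER_NM = 10.0


class PDBParseError(ValueError):
    """Malformed PDB content; carries the offending line number."""


class StructureLookupError(LookupError):
    """Requested model, chain, or residue range is absent."""


@dataclass
class Structure:
    """Heavy-atom protein (or bead-polymer) structure in nm coordinates."""

    atom_names: list[str]
    elements: list[str]
    res_indices: np.ndarray          # int, per atom, as numbered in the source
    res_names: list[str]             # 3-letter codes, per atom
    chains: list[str]                # chain id, per atom
    coords: np.ndarray               # (n_atoms, 3) nm
    title: str = ""
    source: str = ""

    def __post_init__(self) -> None:
        self.res_indices = np.asarray(self.res_indices, dtype=np.int64)
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.shape != (len(self.atom_names), 3):
            raise ValueError("coordinate array shape does not match atom list")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    def residue_keys(self) -> list[tuple[str, int]]:
        """Ordered unique (chain, residue index) keys."""
        seen: dict[tuple[str, int], None] = {}
        for ch, ri in zip(self.chains, self.res_indices):
            seen.setdefault((ch, int(ri)), None)
        return list(seen)

    @property
    def n_residues(self) -> int:
        return len(self.residue_keys())

    def residue_groups(self) -> list[np.ndarray]:
        """Atom-index arrays, one per residue, in residue order."""
        order: dict[tuple[str, int], list[int]] = {}
        for a, (ch, ri) in enumerate(zip(self.chains, self.res_indices)):
            order.setdefault((ch, int(ri)), []).append(a)
        return [np.asarray(v, dtype=np.int64) for v in order.values()]

    def residue_names_per_residue(self) -> list[str]:
        return [self.res_names[g[0]] for g in self.residue_groups()]

    def ca_indices(self) -> np.ndarray:
        """Atom index of the CA atom of each residue, in residue order."""
        out = []
        for g in self.residue_groups():
            hits = [a for a in g if self.atom_names[a] == "CA"]
            if not hits:
                key = (self.chains[g[0]], int(self.res_indices[g[0]]))
                raise StructureLookupError(f"residue {key} has no CA atom")
            out.append(hits[0])
        return np.asarray(out, dtype=np.int64)

    def with_coords(self, coords: np.ndarray) -> "Structure":
        return replace(self, coords=np.asarray(coords, dtype=np.float64))


# ---------------------------------------------------------------------------
# PDB reading / writing
# ---------------------------------------------------------------------------

def _parse_atom_line(line: str, lineno: int):
    try:
        name = line[12:16].strip()
        altloc = line[16].strip()
        res_name = line[17:20].strip()
        chain = line[21].strip() or "A"
        res_seq = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        occ_field = line[54:60].strip()
        occ = float(occ_field) if occ_field else 1.0
        elem = line[76:78].strip() if len(line) >= 78 else ""
    except (ValueError, IndexError) as exc:
        raise PDBParseError(f"malformed ATOM record at line {lineno}: {exc}") from exc
    if not elem:
        elem = rd.element_of(name)
    return name, altloc, res_name, chain, res_seq, (x, y, z), occ, elem.upper()


def parse_pdb(text: str, model_index: int = 0, chain: str | None = None) -> Structure:
    """Parse PDB text into a normalized heavy-atom :class:`Structure`.

    Normalization: hydrogens and deuteriums stripped, HETATM records
    (waters, ligands, ions) dropped, alternate locations resolved to the
    highest occupancy (ties broken in favour of altloc 'A'), coordinates
    converted from Angstrom to nm. For multi-model (NMR) entries
    ``model_index`` selects the model, defaulting to the first.
    """
    models: list[list] = []
    current: list = []
    in_model = False
    title_parts: list[str] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6]
        if rec == "TITLE ":
            title_parts.append(line[10:].strip())
        elif rec == "MODEL ":
            if in_model and current:
                models.append(current)
            current = []
            in_model = True
        elif rec == "ENDMDL":
            models.append(current)
            current = []
            in_model = False
        elif rec == "ATOM  ":
            current.append(_parse_atom_line(line, lineno))
    if current or not models:
        models.append(current)

    if model_index >= len(models):
        raise StructureLookupError(
            f"model {model_index} absent ({len(models)} model(s) present)")
    records = models[model_index]

    if chain is not None:
        records = [r for r in records if r[3] == chain]
        if not records:
            raise StructureLookupError(f"chain {chain!r} absent from model")

    # Resolve altlocs: keep the highest-occupancy variant of each atom.
    best: dict[tuple, tuple] = {}
    order: list[tuple] = []
    for r in records:
        name, altloc, res_name, ch, res_seq, xyz, occ, elem = r
        key = (ch, res_seq, name)
        rank = (-occ, altloc if altloc else "A")
        if key not in best:
            best[key] = (rank, r)
            order.append(key)
        elif rank < best[key][0]:
            best[key] = (rank, r)

    names, elems, ridx, rnames, chains, xyzs = [], [], [], [], [], []
    for key in order:
        name, _, res_name, ch, res_seq, xyz, _, elem = best[key][1]
        if elem in ("H", "D"):
            continue
        if res_name not in rd.THREE_TO_ONE:
            raise PDBParseError(f"unknown residue type {res_name!r}")
        names.append(name)
        elems.append(elem)
        rnames.append(res_name)
        ridx.append(res_seq)
        chains.append(ch)
        xyzs.append(xyz)
    coords = np.asarray(xyzs, dtype=np.float64).reshape(-1, 3) / A_PER_NM
    return Structure(names, elems, np.asarray(ridx), rnames, chains, coords,
                     title=" ".join(title_parts), source="pdb")


def write_structure(s: Structure, multi_model: list[np.ndarray] | None = None) -> str:
    """Serialize a structure to PDB text (multi-model if frames are given).

    Round-trip safe with :func:`parse_pdb` to the PDB coordinate precision
    of 1e-3 Angstrom.
    """
    if s.n_atoms == 0:
        raise ValueError("cannot write an empty structure")
    frames = multi_model if multi_model is not None else [s.coords]
    lines: list[str] = []
    if s.title:
        lines.append(f"TITLE     {s.title}")
    for m, frame in enumerate(frames, start=1):
        frame = np.asarray(frame, dtype=np.float64)
        if frame.shape != (s.n_atoms, 3):
            raise ValueError("frame shape does not match structure")
        if len(frames) > 1:
            lines.append(f"MODEL     {m:4d}")
        for a in range(s.n_atoms):
            name = s.atom_names[a]
            pdb_name = f" {name:<3s}" if len(name) < 4 else name
            x, y, z = frame[a] * A_PER_NM
            lines.append(
                f"ATOM  {a + 1:5d} {pdb_name}{'':1s}{s.res_names[a]:>3s} "
                f"{s.chains[a]:1s}{int(s.res_indices[a]):4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
                f"{s.elements[a]:>2s}")
        if len(frames) > 1:
            lines.append("ENDMDL")
    lines.append("END")
    return "\n".join(lines) + "\n"


def extract_fragment(s: Structure, first_residue: int, last_residue: int) -> Structure:
    """Contiguous sub-structure between two residue numbers (inclusive).

    Residue numbering of the source is preserved.
    """
    if last_residue < first_residue:
        raise ValueError("empty residue range")
    mask = (s.res_indices >= first_residue) & (s.res_indices <= last_residue)
    if not np.any(mask):
        raise StructureLookupError(
            f"residue range {first_residue}-{last_residue} absent")
    idx = np.flatnonzero(mask)
    return Structure(
        [s.atom_names[i] for i in idx],
        [s.elements[i] for i in idx],
        s.res_indices[idx],
        [s.res_names[i] for i in idx],
        [s.chains[i] for i in idx],
        s.coords[idx],
        title=s.title,
        source=s.source,
    )


# ---------------------------------------------------------------------------
# Synthetic fixtures
# ---------------------------------------------------------------------------

# Ideal backbone internal coordinates (nm / degrees).
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O = 0.1458, 0.1525, 0.1329, 0.1231
_A_C_N_CA, _A_N_CA_C, _A_CA_C_N, _A_CA_C_O = 121.7, 111.2, 116.2, 120.8
HELIX_PHI, HELIX_PSI, HELIX_OMEGA = -57.0, -47.0, 180.0


def _place(a: np.ndarray, b: np.ndarray, c: np.ndarray,
           bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Natural-extension-reference-frame placement of atom d from a-b-c."""
    theta = math.radians(angle_deg)
    phi = math.radians(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-12:
        # a,b,c collinear: pick an arbitrary perpendicular reference
        ref = np.array([1.0, 0.0, 0.0])
        if abs(bc[0]) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        n = np.cross(ref, bc)
        nn = np.linalg.norm(n)
    n /= nn
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * math.cos(theta),
        bond * math.sin(theta) * math.cos(phi),
        bond * math.sin(theta) * math.sin(phi),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


# Rough single-bond lengths for generic side-chain placement (nm).
_SC_BOND = {("C", "C"): 0.152, ("C", "N"): 0.147, ("C", "O"): 0.143,
            ("C", "S"): 0.181}


def _sc_bond_length(e1: str, e2: str) -> float:
    return _SC_BOND.get((e1, e2)) or _SC_BOND.get((e2, e1)) or 0.152


def build_ideal_helix(sequence: str) -> Structure:
    """Deterministic all-heavy-atom ideal alpha-helix from a 1-letter sequence.

    The backbone uses ideal helical dihedrals (phi, psi, omega) =
    (-57, -47, 180) degrees with standard peptide bond geometry; side
    chains are grown in extended (trans) rotamers with approximately
    tetrahedral branching, rings curled with cis dihedrals. Geometry is
    idealized, not energy-minimized.
    """
    if not sequence:
        raise ValueError("empty sequence")
    try:
        seq3 = [rd.ONE_TO_THREE[c] for c in sequence.upper()]
    except KeyError as exc:
        raise ValueError(f"unknown residue letter {exc.args[0]!r}") from exc

    names: list[str] = []
    elems: list[str] = []
    ridx: list[int] = []
    rnames: list[str] = []
    pos: list[np.ndarray] = []
    backbone: list[dict] = []  # per-residue dict of backbone positions

    for i, res in enumerate(seq3):
        if i == 0:
            n = np.zeros(3)
            ca = np.array([_B_N_CA, 0.0, 0.0])
            theta = math.radians(_A_N_CA_C)
            c = ca + _B_CA_C * np.array([-math.cos(theta), math.sin(theta), 0.0])
        else:
            prev = backbone[-1]
            n = _place(prev["N"], prev["CA"], prev["C"], _B_C_N, _A_CA_C_N, HELIX_PSI)
            ca = _place(prev["CA"], prev["C"], n, _B_N_CA, _A_C_N_CA, HELIX_OMEGA)
            c = _place(prev["C"], n, ca, _B_CA_C, _A_N_CA_C, HELIX_PHI)
        # carbonyl O anti to the next amide nitrogen
        o = _place(n, ca, c, _B_C_O, _A_CA_C_O, HELIX_PSI + 180.0)
        bb = {"N": n, "CA": ca, "C": c, "O": o}
        backbone.append(bb)

        placed = dict(bb)
        if res != "GLY":
            # CB off the N/C bisector, on the L-configuration side
            u = bb["N"] - ca
            v = bb["C"] - ca
            u /= np.linalg.norm(u)
            v /= np.linalg.norm(v)
            b1 = -(u + v)
            b1 /= np.linalg.norm(b1)
            b2 = np.cross(v, u)
            b2 /= np.linalg.norm(b2)
            cb_dir = b1 * math.cos(math.radians(54.0)) + b2 * math.sin(math.radians(54.0))
            placed["CB"] = ca + 0.153 * cb_dir

        # Grow the remaining side chain along the bond tree.
        adj: dict[str, list[str]] = {}
        for a1, a2 in rd.residue_bonds(res):
            adj.setdefault(a1, []).append(a2)
            adj.setdefault(a2, []).append(a1)
        ring_bonds = _ring_bonds(adj)
        parent = {"CB": "CA", "CA": "N"}
        for atom in rd.SIDECHAIN_ATOMS[res]:
            if atom in placed:
                continue
            par = next(p for p in adj[atom] if p in placed)
            gp = parent.get(par, "CA")
            ggp = parent.get(gp, "N")
            placed_children = [x for x in adj[par]
                               if x != gp and x in placed and x != atom]
            in_ring = frozenset((par, atom)) in ring_bonds
            dihe = 0.0 if in_ring else 180.0 + 120.0 * len(placed_children)
            ang = 120.0 if in_ring else 111.0
            e_par = rd.element_of(par)
            e_new = rd.element_of(atom)
            placed[atom] = _place(placed[ggp], placed[gp], placed[par],
                                  _sc_bond_length(e_par, e_new), ang, dihe)
            parent[atom] = par
        for atom in rd.heavy_atoms(res):
            names.append(atom)
            elems.append(rd.element_of(atom))
            ridx.append(i + 1)
            rnames.append(res)
            pos.append(placed[atom])

    coords = np.vstack(pos)
    chains = ["A"] * len(names)
    return Structure(names, elems, np.asarray(ridx), rnames, chains, coords,
                     title=f"ideal helix {sequence.upper()}", source="fixture:helix")


def _ring_bonds(adj: dict[str, list[str]]) -> set[frozenset]:
    """Bonds that lie on a cycle of the residue bond graph."""
    rings: set[frozenset] = set()
    edges = {frozenset((a, b)) for a, nbrs in adj.items() for b in nbrs}
    for edge in edges:
        a, b = tuple(edge)
        # edge is in a ring iff a and b stay connected without it
        stack, seen = [a], {a}
        while stack:
            cur = stack.pop()
            if cur == b:
                rings.add(edge)
                break
            for nxt in adj.get(cur, []):
                if frozenset((cur, nxt)) == edge or nxt in seen:
                    continue
                seen.add(nxt)
                stack.append(nxt)
    return rings


POLYMER_BOND_NM = 0.38


def build_two_state_polymer(n_beads: int, seed: int) -> tuple[Structure, Structure]:
    """Two deterministic conformations of one bead chain: hairpin and extended.

    Each bead is a single-CA pseudo-residue with bond length 0.38 nm. The
    hairpin folds the chain back on itself through a two-bond turn (arm
    separation ~0.66 nm) with a small seeded out-of-plane jitter so that
    no dihedral of the native state is degenerate; the extended state is
    an exactly straight chain (end-to-end distance (n-1) x 0.38 nm).
    """
    if n_beads < 4:
        raise ValueError("n_beads must be >= 4")
    b = POLYMER_BOND_NM
    rng = np.random.default_rng(seed)

    # extended: straight chain along x
    ext = np.zeros((n_beads, 3))
    ext[:, 0] = np.arange(n_beads) * b

    # hairpin: bond directions 0deg (arm 1), 60/120deg (turn), 180deg (arm 2)
    n_arm1 = (n_beads - 2) // 2
    angles = [0.0] * (n_arm1 - 1) + [60.0, 120.0]
    angles += [180.0] * (n_beads - 1 - len(angles))
    hp = np.zeros((n_beads, 3))
    for i, ang in enumerate(angles):
        a = math.radians(ang)
        hp[i + 1] = hp[i] + b * np.array([math.cos(a), math.sin(a), 0.0])
    hp[:, 2] += rng.normal(0.0, 0.02, size=n_beads)  # break planarity

    def _mk(coords: np.ndarray, tag: str) -> Structure:
        n = coords.shape[0]
        return Structure(
            ["CA"] * n, ["C"] * n, np.arange(1, n + 1), ["GLY"] * n,
            ["A"] * n, coords, title=f"two-state polymer ({tag})",
            source=f"fixture:polymer-{tag}")

    return _mk(hp, "hairpin"), _mk(ext, "extended")
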