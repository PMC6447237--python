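"""Amino-acid reference data: codes, heavy-atom bond graphs, formulas, volumes.

All quantities refer to residues as they occur inside a peptide chain
(i.e. the free amino acid minus one water). Volumes are mean residue
volumes in A^3 from standard packing analyses of protein interiors.
"""

from __future__ import annotations

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

BACKBONE_ATOMS = ("N", "CA", "C", "O")
BACKBONE_BONDS = (("N", "CA"), ("CA", "C"), ("C", "O"))

# Heavy side-chain atoms in placement order (parents appear before children).
SIDECHAIN_ATOMS = {
    "ALA": ["CB"],
    "ARG": ["CB", "CG", "CD", "NE", "CZ", "NH1", "NH2"],
    "ASN": ["CB", "CG", "OD1", "ND2"],
    "ASP": ["CB", "CG", "OD1", "OD2"],
    "CYS": ["CB", "SG"],
    "GLN": ["CB", "CG", "CD", "OE1", "NE2"],
    "GLU": ["CB", "CG", "CD", "OE1", "OE2"],
    "GLY": [],
    "HIS": ["CB", "CG", "ND1", "CD2", "CE1", "NE2"],
    "ILE": ["CB", "CG1", "CG2", "CD1"],
    "LEU": ["CB", "CG", "CD1", "CD2"],
    "LYS": ["CB", "CG", "CD", "CE", "NZ"],
    "MET": ["CB", "CG", "SD", "CE"],
    "PHE": ["CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"],
    "PRO": ["CB", "CG", "CD"],
    "SER": ["CB", "OG"],
    "THR": ["CB", "OG1", "CG2"],
    "TRP": ["CB", "CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"],
    "TYR": ["CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ", "OH"],
    "VAL": ["CB", "CG1", "CG2"],
}

# Intra-residue heavy-atom bonds beyond the backbone (CA-CB included here).
SIDECHAIN_BONDS = {
    "ALA": [("CA", "CB")],
    "ARG": [("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "NE"),
            ("NE", "CZ"), ("CZ", "NH1"), ("CZ", "NH2")],
    "ASN": [("CA", "CB"), ("CB", "CG"), ("CG", "OD1"), ("CG", "ND2")],
    "ASP": [("CA", "CB"), ("CB", "CG"), ("CG", "OD1"), ("CG", "OD2")],
    "CYS": [("CA", "CB"), ("CB", "SG")],
    "GLN": [("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "OE1"),
            ("CD", "NE2")],
    "GLU": [("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "OE1"),
            ("CD", "OE2")],
    "GLY": [],
    "HIS": [("CA", "CB"), ("CB", "CG"), ("CG", "ND1"), ("CG", "CD2"),
            ("ND1", "CE1"), ("CD2", "NE2"), ("CE1", "NE2")],
    "ILE": [("CA", "CB"), ("CB", "CG1"), ("CB", "CG2"), ("CG1", "CD1")],
    "LEU": [("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CG", "CD2")],
    "LYS": [("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "CE"),
            ("CE", "NZ")],
    "MET": [("CA", "CB"), ("CB", "CG"), ("CG", "SD"), ("SD", "CE")],
    "PHE": [("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CG", "CD2"),
            ("CD1", "CE1"), ("CD2", "CE2"), ("CE1", "CZ"), ("CE2", "CZ")],
    "PRO": [("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "N")],
    "SER": [("CA", "CB"), ("CB", "OG")],
    "THR": [("CA", "CB"), ("CB", "OG1"), ("CB", "CG2")],
    "TRP": [("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CG", "CD2"),
            ("CD1", "NE1"), ("NE1", "CE2"), ("CD2", "CE2"), ("CD2", "CE3"),
            ("CE2", "CZ2"), ("CE3", "CZ3"), ("CZ2", "CH2"), ("CZ3", "CH2")],
    "TYR": [("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CG", "CD2"),
            ("CD1", "CE1"), ("CD2", "CE2"), ("CE1", "CZ"), ("CE2", "CZ"),
            ("CZ", "OH")],
    "VAL": [("CA", "CB"), ("CB", "CG1"), ("CB", "CG2")],
}

# Chemical formula of the in-chain residue as (C, H, N, O, S) atom counts.
RESIDUE_FORMULA = {
    "ALA": (3, 5, 1, 1, 0),
    "ARG": (6, 12, 4, 1, 0),
    "ASN": (4, 6, 2, 2, 0),
    "ASP": (4, 5, 1, 3, 0),
    "CYS": (3, 5, 1, 1, 1),
    "GLN": (5, 8, 2, 2, 0),
    "GLU": (5, 7, 1, 3, 0),
    "GLY": (2, 3, 1, 1, 0),
    "HIS": (6, 7, 3, 1, 0),
    "ILE": (6, 11, 1, 1, 0),
    "LEU": (6, 11, 1, 1, 0),
    "LYS": (6, 12, 2, 1, 0),
    "MET": (5, 9, 1, 1, 1),
    "PHE": (9, 9, 1, 1, 0),
    "PRO": (5, 7, 1, 1, 0),
    "SER": (3, 5, 1, 2, 0),
    "THR": (4, 7, 1, 2, 0),
    "TRP": (11, 10, 2, 1, 0),
    "TYR": (9, 9, 1, 2, 0),
    "VAL": (5, 9, 1, 1, 0),
}

_ELECTRONS_PER_ATOM = (6, 1, 7, 8, 16)  # C, H, N, O, S

# Mean residue volumes in A^3 (protein-interior packing values).
RESIDUE_VOLUME_A3 = {
    "ALA": 88.6, "ARG": 173.4, "ASN": 114.1, "ASP": 111.1, "CYS": 108.5,
    "GLN": 143.8, "GLU": 138.4, "GLY": 60.1, "HIS": 153.2, "ILE": 166.7,
    "LEU": 166.7, "LYS": 168.6, "MET": 162.9, "PHE": 189.9, "PRO": 112.7,
    "SER": 89.0, "THR": 116.1, "TRP": 227.8, "TYR": 193.6, "VAL": 140.0,
}


def residue_electrons(res_name: str) -> int:
    """Total electron count of the neutral in-chain residue."""
    counts = RESIDUE_FORMULA[res_name]
    return sum(n * z for n, z in zip(counts, _ELECTRONS_PER_ATOM))


def heavy_atoms(res_name: str) -> list[str]:
    """Heavy atoms of a residue in canonical order (backbone then side chain)."""
    return list(BACKBONE_ATOMS) + SIDECHAIN_ATOMS[res_name]


def residue_bonds(res_name: str) -> list[tuple[str, str]]:
    """All intra-residue heavy-atom bonds (backbone + side chain)."""
    return list(BACKBONE_BONDS) + SIDECHAIN_BONDS[res_name]


def element_of(atom_name: str) -> str:
    """Infer the element from a PDB atom name (heavy protein atoms only)."""
    stripped = atom_name.strip().lstrip("0123456789")
    if not stripped:
        raise ValueError(f"cannot infer element from atom name {atom_name!r}")
    return stripped[0].upper()
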