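"""Residue chemistry tables: amino-acid codes, idealized side-chain internal
coordinates, rotatable chi definitions, and donor/acceptor role assignments.

Internal coordinates use standard stereochemical-dictionary values
(Engh/Huber-type bond lengths and angles). Each side-chain atom is defined by
a z-matrix entry (reference triple A-B-C, bond C-X, angle B-C-X, torsion
A-B-C-X); torsions are either fixed (ring/branch geometry) or expressed as an
offset from a rotatable chi dihedral.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

AA_3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA_1TO3 = {v: k for k, v in AA_3TO1.items()}
CANONICAL_AA3 = frozenset(AA_3TO1)

RNA_RESNAMES = frozenset({"A", "U", "G", "C", "I"})
DNA_RESNAMES = frozenset({"DA", "DT", "DG", "DC"})
WATER_RESNAMES = frozenset({"HOH", "WAT", "DOD"})

BACKBONE_ATOMS = ("N", "CA", "C", "O")

# -- z-matrix torsion spec: fixed degrees, or ("chi", k, offset_degrees) ----
Torsion = Union[float, tuple]


@dataclass(frozen=True)
class ZEntry:
    name: str
    refs: tuple[str, str, str]  # A, B, C; atom bonded to C
    bond: float                 # Angstrom
    angle: float                # degrees, B-C-atom
    torsion: Torsion            # degrees, A-B-C-atom


def _z(name, a, b, c, bond, angle, torsion) -> ZEntry:
    return ZEntry(name, (a, b, c), bond, angle, torsion)


# CB is common to all non-Gly residues: improper torsion C-N-CA-CB = -120
# fixes the L-alpha configuration.
_CB = _z("CB", "C", "N", "CA", 1.530, 110.5, -120.0)

#: Per-residue side-chain construction past CB. chi1 = N-CA-CB-X.
SIDECHAIN_ZMATRIX: dict[str, list[ZEntry]] = {
    "GLY": [],
    "ALA": [_CB],
    "SER": [_CB, _z("OG", "N", "CA", "CB", 1.417, 110.8, ("chi", 1, 0.0))],
    "CYS": [_CB, _z("SG", "N", "CA", "CB", 1.808, 114.0, ("chi", 1, 0.0))],
    "THR": [_CB,
            _z("OG1", "N", "CA", "CB", 1.433, 109.6, ("chi", 1, 0.0)),
            _z("CG2", "N", "CA", "CB", 1.521, 110.5, ("chi", 1, -120.0))],
    "VAL": [_CB,
            _z("CG1", "N", "CA", "CB", 1.521, 110.5, ("chi", 1, 0.0)),
            _z("CG2", "N", "CA", "CB", 1.521, 110.5, ("chi", 1, 120.0))],
    "LEU": [_CB,
            _z("CG", "N", "CA", "CB", 1.530, 116.3, ("chi", 1, 0.0)),
            _z("CD1", "CA", "CB", "CG", 1.521, 110.7, ("chi", 2, 0.0)),
            _z("CD2", "CA", "CB", "CG", 1.521, 110.7, ("chi", 2, 120.0))],
    "ILE": [_CB,
            _z("CG1", "N", "CA", "CB", 1.530, 110.4, ("chi", 1, 0.0)),
            _z("CG2", "N", "CA", "CB", 1.521, 110.5, ("chi", 1, -120.0)),
            _z("CD1", "CA", "CB", "CG1", 1.513, 113.8, ("chi", 2, 0.0))],
    "MET": [_CB,
            _z("CG", "N", "CA", "CB", 1.520, 114.1, ("chi", 1, 0.0)),
            _z("SD", "CA", "CB", "CG", 1.803, 112.7, ("chi", 2, 0.0)),
            _z("CE", "CB", "CG", "SD", 1.791, 100.9, ("chi", 3, 0.0))],
    "PRO": [  # ring closure: fixed pucker chosen so CD lands ~1.47 A from N
            _z("CB", "C", "N", "CA", 1.530, 103.0, -120.0),
            _z("CG", "N", "CA", "CB", 1.495, 104.5, ("chi", 1, 0.0)),
            _z("CD", "CA", "CB", "CG", 1.507, 105.5, ("chi", 2, 0.0))],
    "PHE": [_CB,
            _z("CG", "N", "CA", "CB", 1.502, 113.8, ("chi", 1, 0.0)),
            _z("CD1", "CA", "CB", "CG", 1.384, 120.8, ("chi", 2, 0.0)),
            _z("CD2", "CA", "CB", "CG", 1.384, 120.8, ("chi", 2, 180.0)),
            _z("CE1", "CB", "CG", "CD1", 1.382, 120.8, 180.0),
            _z("CE2", "CB", "CG", "CD2", 1.382, 120.8, 180.0),
            _z("CZ", "CG", "CD1", "CE1", 1.382, 120.0, 0.0)],
    "TYR": [_CB,
            _z("CG", "N", "CA", "CB", 1.512, 113.9, ("chi", 1, 0.0)),
            _z("CD1", "CA", "CB", "CG", 1.389, 120.8, ("chi", 2, 0.0)),
            _z("CD2", "CA", "CB", "CG", 1.389, 120.8, ("chi", 2, 180.0)),
            _z("CE1", "CB", "CG", "CD1", 1.382, 121.2, 180.0),
            _z("CE2", "CB", "CG", "CD2", 1.382, 121.2, 180.0),
            _z("CZ", "CG", "CD1", "CE1", 1.378, 119.6, 0.0),
            _z("OH", "CD1", "CE1", "CZ", 1.376, 119.9, 180.0)],
    "TRP": [_CB,
            _z("CG", "N", "CA", "CB", 1.498, 113.6, ("chi", 1, 0.0)),
            _z("CD1", "CA", "CB", "CG", 1.365, 126.9, ("chi", 2, 0.0)),
            _z("CD2", "CA", "CB", "CG", 1.433, 126.8, ("chi", 2, 180.0)),
            _z("NE1", "CB", "CG", "CD1", 1.374, 110.2, 180.0),
            _z("CE2", "CB", "CG", "CD2", 1.409, 107.2, 180.0),
            _z("CE3", "CB", "CG", "CD2", 1.398, 133.9, 0.0),
            _z("CZ2", "CG", "CD2", "CE2", 1.394, 122.4, 180.0),
            _z("CZ3", "CG", "CD2", "CE3", 1.382, 118.6, 180.0),
            _z("CH2", "CD2", "CE2", "CZ2", 1.368, 117.5, 0.0)],
    "ASP": [_CB,
            _z("CG", "N", "CA", "CB", 1.516, 112.6, ("chi", 1, 0.0)),
            _z("OD1", "CA", "CB", "CG", 1.249, 118.4, ("chi", 2, 0.0)),
            _z("OD2", "CA", "CB", "CG", 1.249, 118.4, ("chi", 2, 180.0))],
    "ASN": [_CB,
            _z("CG", "N", "CA", "CB", 1.516, 112.6, ("chi", 1, 0.0)),
            _z("OD1", "CA", "CB", "CG", 1.231, 120.8, ("chi", 2, 0.0)),
            _z("ND2", "CA", "CB", "CG", 1.328, 116.4, ("chi", 2, 180.0))],
    "GLU": [_CB,
            _z("CG", "N", "CA", "CB", 1.520, 114.1, ("chi", 1, 0.0)),
            _z("CD", "CA", "CB", "CG", 1.516, 112.6, ("chi", 2, 0.0)),
            _z("OE1", "CB", "CG", "CD", 1.249, 118.4, ("chi", 3, 0.0)),
            _z("OE2", "CB", "CG", "CD", 1.249, 118.4, ("chi", 3, 180.0))],
    "GLN": [_CB,
            _z("CG", "N", "CA", "CB", 1.520, 114.1, ("chi", 1, 0.0)),
            _z("CD", "CA", "CB", "CG", 1.516, 112.6, ("chi", 2, 0.0)),
            _z("OE1", "CB", "CG", "CD", 1.231, 120.8, ("chi", 3, 0.0)),
            _z("NE2", "CB", "CG", "CD", 1.328, 116.4, ("chi", 3, 180.0))],
    "LYS": [_CB,
            _z("CG", "N", "CA", "CB", 1.520, 114.1, ("chi", 1, 0.0)),
            _z("CD", "CA", "CB", "CG", 1.520, 111.3, ("chi", 2, 0.0)),
            _z("CE", "CB", "CG", "CD", 1.520, 111.3, ("chi", 3, 0.0)),
            _z("NZ", "CG", "CD", "CE", 1.489, 111.9, ("chi", 4, 0.0))],
    "ARG": [_CB,
            _z("CG", "N", "CA", "CB", 1.520, 114.1, ("chi", 1, 0.0)),
            _z("CD", "CA", "CB", "CG", 1.520, 111.3, ("chi", 2, 0.0)),
            _z("NE", "CB", "CG", "CD", 1.461, 112.0, ("chi", 3, 0.0)),
            _z("CZ", "CG", "CD", "NE", 1.329, 124.2, ("chi", 4, 0.0)),
            _z("NH1", "CD", "NE", "CZ", 1.326, 121.0, 180.0),
            _z("NH2", "CD", "NE", "CZ", 1.326, 121.0, 0.0)],
    "HIS": [_CB,
            _z("CG", "N", "CA", "CB", 1.497, 113.8, ("chi", 1, 0.0)),
            _z("ND1", "CA", "CB", "CG", 1.351, 120.3, ("chi", 2, 0.0)),
            _z("CD2", "CA", "CB", "CG", 1.338, 129.9, ("chi", 2, 180.0)),
            _z("CE1", "CB", "CG", "ND1", 1.337, 107.9, 180.0),
            _z("NE2", "CB", "CG", "CD2", 1.374, 105.3, 180.0)],
}

#: Number of grid-rotatable chi dihedrals per residue. Proline's ring is
#: built at a single fixed pucker (chi fixed below), so it contributes none.
N_CHI = {
    "GLY": 0, "ALA": 0, "PRO": 0,
    "SER": 1, "CYS": 1, "THR": 1, "VAL": 1,
    "LEU": 2, "ILE": 2, "ASP": 2, "ASN": 2, "PHE": 2, "TYR": 2,
    "TRP": 2, "HIS": 2,
    "MET": 3, "GLU": 3, "GLN": 3,
    "LYS": 4, "ARG": 4,
}

#: Fixed chi values for residues whose chis are not searched (proline ring
#: pucker; closes the ring with CD ~1.5 A from N).
FIXED_CHI = {"PRO": (-28.0, 35.0)}

#: Residues whose final chi rotates a planar terminal amide/carboxyl group:
#: the rotamer grid for that chi is extended with 180-degree flips.
TERMINAL_FLIP_RESIDUES = frozenset({"ASN", "ASP", "GLN", "GLU"})

#: Atoms defining chi_k as dihedral (a, b, c, d); d is the first atom whose
#: torsion is ("chi", k, 0).
CHI_DEFINITIONS: dict[str, list[tuple[str, str, str, str]]] = {}
for _res, _entries in SIDECHAIN_ZMATRIX.items():
    _defs = []
    for _e in _entries:
        if isinstance(_e.torsion, tuple) and _e.torsion[2] == 0.0:
            _defs.append((*_e.refs, _e.name))
    CHI_DEFINITIONS[_res] = _defs


def sidechain_atom_names(resname: str) -> tuple[str, ...]:
    """Canonical heavy side-chain atom names (CB onward) for a residue."""
    if resname not in SIDECHAIN_ZMATRIX:
        raise KeyError(f"no side-chain template for residue {resname!r}")
    return tuple(e.name for e in SIDECHAIN_ZMATRIX[resname])


def element_of(atom_name: str, resname: str = "") -> str:
    """Best-effort element symbol from a PDB-convention atom name."""
    stripped = atom_name.strip().lstrip("0123456789")
    if not stripped:
        return ""
    first = stripped[0].upper()
    if first in ("C", "N", "O", "S", "P", "H", "D"):
        return "H" if first == "D" else first
    return stripped[:1].upper()


# --------------------------------------------------------------------------
# Donor / acceptor roles (heavy atoms only; roles refer to the hydrogen the
# heavy atom would bear).  Sulfur entries are chemically marginal and are
# surfaced separately so callers can exclude them.

DONOR, ACCEPTOR, BOTH, NONE = "donor", "acceptor", "both", "none"

_SIDECHAIN_ROLES: dict[str, dict[str, str]] = {
    "SER": {"OG": BOTH},
    "THR": {"OG1": BOTH},
    "TYR": {"OH": BOTH},
    "CYS": {"SG": BOTH},       # sulfur: weak, nonstandard
    "MET": {"SD": ACCEPTOR},   # sulfur: weak, nonstandard
    "ASN": {"OD1": ACCEPTOR, "ND2": DONOR},
    "GLN": {"OE1": ACCEPTOR, "NE2": DONOR},
    "ASP": {"OD1": ACCEPTOR, "OD2": ACCEPTOR},
    "GLU": {"OE1": ACCEPTOR, "OE2": ACCEPTOR},
    "LYS": {"NZ": DONOR},
    "ARG": {"NE": DONOR, "NH1": DONOR, "NH2": DONOR},
    "HIS": {"ND1": BOTH, "NE2": BOTH},
    "TRP": {"NE1": DONOR},
}

_RNA_SUGAR_PHOSPHATE_ROLES = {
    "P": NONE,
    "OP1": ACCEPTOR, "OP2": ACCEPTOR, "OP3": ACCEPTOR,
    "O5'": ACCEPTOR, "O3'": ACCEPTOR, "O4'": ACCEPTOR,
    "O2'": BOTH,
}

_RNA_BASE_ROLES: dict[str, dict[str, str]] = {
    "A": {"N1": ACCEPTOR, "N3": ACCEPTOR, "N6": DONOR, "N7": ACCEPTOR},
    "G": {"N1": DONOR, "N2": DONOR, "N3": ACCEPTOR, "O6": ACCEPTOR,
          "N7": ACCEPTOR},
    "C": {"O2": ACCEPTOR, "N3": ACCEPTOR, "N4": DONOR},
    "U": {"O2": ACCEPTOR, "N3": DONOR, "O4": ACCEPTOR},
}

SULFUR_ROLE_ATOMS = frozenset({("CYS", "SG"), ("MET", "SD")})


def polar_role(resname: str, atom_name: str) -> str:
    """Donor/acceptor role of a heavy atom, or "none".

    Backbone amide N is a donor (except proline, whose N bears no hydrogen);
    backbone carbonyl O and terminal OXT are acceptors. Unknown combinations
    map to "none".
    """
    resname = resname.strip().upper()
    atom_name = atom_name.strip()
    if resname in CANONICAL_AA3:
        if atom_name == "N":
            return NONE if resname == "PRO" else DONOR
        if atom_name in ("O", "OXT"):
            return ACCEPTOR
        return _SIDECHAIN_ROLES.get(resname, {}).get(atom_name, NONE)
    if resname in RNA_RESNAMES:
        if atom_name in _RNA_SUGAR_PHOSPHATE_ROLES:
            return _RNA_SUGAR_PHOSPHATE_ROLES[atom_name]
        return _RNA_BASE_ROLES.get(resname, {}).get(atom_name, NONE)
    return NONE
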