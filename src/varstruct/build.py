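"""Construction of idealized protein geometry from internal coordinates.

Backbones are chained with the NeRF construction from ideal peptide bond
lengths/angles; side chains are grown from the z-matrix templates in
:mod:`varstruct.chemistry` given a vector of chi dihedrals.
"""

from __future__ import annotations

import numpy as np

from . import geometry
from .chemistry import (CHI_DEFINITIONS, FIXED_CHI, N_CHI,
                        SIDECHAIN_ZMATRIX)
from .model import Residue

# ideal peptide geometry (Engh/Huber-type)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8


def place_cb(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Ideal tetrahedral CB from backbone N/CA/C (L-configuration)."""
    return geometry.place_atom(c, n, ca, 1.530, 110.5, -120.0)


def build_backbone(n_residues: int, phi: float, psi: float,
                   omega: float = 180.0) -> list[dict[str, np.ndarray]]:
    """Backbone N/CA/C/O coordinates for a chain at uniform dihedrals."""
    if n_residues < 1:
        raise ValueError("need at least one residue")
    res: list[dict[str, np.ndarray]] = []
    n = np.zeros(3)
    ca = np.array([BOND_N_CA, 0.0, 0.0])
    dummy = np.array([0.0, -1.0, 0.0])
    c = geometry.place_atom(dummy, n, ca, BOND_CA_C, ANGLE_N_CA_C, 120.0)
    res.append({"N": n, "CA": ca, "C": c})
    for _ in range(n_residues - 1):
        prev = res[-1]
        n_next = geometry.place_atom(prev["N"], prev["CA"], prev["C"],
                                     BOND_C_N, ANGLE_CA_C_N, psi)
        ca_next = geometry.place_atom(prev["CA"], prev["C"], n_next,
                                      BOND_N_CA, ANGLE_C_N_CA, omega)
        c_next = geometry.place_atom(prev["C"], n_next, ca_next,
                                     BOND_CA_C, ANGLE_N_CA_C, phi)
        # carbonyl O anti to the next amide N
        prev["O"] = geometry.place_atom(n_next, prev["CA"], prev["C"],
                                        BOND_C_O, ANGLE_CA_C_O, 180.0)
        res.append({"N": n_next, "CA": ca_next, "C": c_next})
    last = res[-1]
    last["O"] = geometry.place_atom(last["N"], last["CA"], last["C"],
                                    BOND_C_O, ANGLE_CA_C_O, psi + 180.0)
    return res


def build_sidechain(resname: str, n: np.ndarray, ca: np.ndarray,
                    c: np.ndarray, chis: tuple[float, ...] = (),
                    ) -> dict[str, np.ndarray]:
    """Grow the heavy side-chain atoms of ``resname`` onto a backbone.

    ``chis`` supplies the rotatable dihedrals (degrees); residues with fixed
    internal chis (proline) ignore it. Returns atom name -> position,
    in template order starting at CB. Glycine returns an empty dict.
    """
    if resname not in SIDECHAIN_ZMATRIX:
        raise KeyError(f"no side-chain template for residue {resname!r}")
    expected = N_CHI[resname]
    if len(chis) != expected:
        raise ValueError(f"{resname} takes {expected} chi angles, got {len(chis)}")
    chi_values = FIXED_CHI.get(resname, tuple(chis))
    coords: dict[str, np.ndarray] = {"N": np.asarray(n, float),
                                     "CA": np.asarray(ca, float),
                                     "C": np.asarray(c, float)}
    out: dict[str, np.ndarray] = {}
    for entry in SIDECHAIN_ZMATRIX[resname]:
        tors = entry.torsion
        if isinstance(tors, tuple):
            _, k, offset = tors
            tors = chi_values[k - 1] + offset
        a, b, cref = (coords[r] for r in entry.refs)
        pos = geometry.place_atom(a, b, cref, entry.bond, entry.angle, tors)
        coords[entry.name] = pos
        out[entry.name] = pos
    return out


def measure_chis(residue: Residue) -> tuple[float, ...]:
    """Observed chi dihedrals of a residue (degrees); only as many as the
    present atoms allow."""
    defs = CHI_DEFINITIONS.get(residue.name, [])
    n_rot = N_CHI.get(residue.name, 0)
    chis = []
    for a, b, c, d in defs[:n_rot]:
        if not all(residue.has_atom(x) for x in (a, b, c, d)):
            break
        chis.append(geometry.dihedral(residue.atom(a).pos, residue.atom(b).pos,
                                      residue.atom(c).pos, residue.atom(d).pos))
    return tuple(chis)
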