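"""Deterministic synthetic structures with known geometry.

These fixtures stand in for a deposited macromolecular complex so that every
pipeline stage — parsing, mutagenesis, contact detection, diffing — can be
exercised against ground truth that is constructed, not curated: idealized
alpha-helices with their backbone hydrogen-bond ladder, two-chain fixtures
with engineered donor-acceptor pairs at chosen distances, and a minimal
protein-RNA contact fixture. The geometry is idealized, not biological; no
attempt is made to mimic any particular fold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import geometry
from .build import build_backbone, build_sidechain
from .chemistry import AA_1TO3, N_CHI, RNA_RESNAMES
from .model import Atom, Chain, Provenance, Residue, StructureModel

IDEAL_HELIX = (-57.0, -47.0, 180.0)  # phi, psi, omega


class FixtureConstructionError(ValueError):
    pass


@dataclass(frozen=True)
class EngineeredContact:
    """One donor-acceptor pair to be realized at an exact distance."""
    residue_a: int       # auth number in chain A
    atom_a: str
    residue_b: int       # auth number in chain B
    atom_b: str
    distance: float      # Angstrom

    def __post_init__(self):
        if not (1.5 < self.distance < 10.0):
            raise FixtureConstructionError(
                f"engineered distance {self.distance} outside (1.5, 10) A")


@dataclass(frozen=True)
class FixtureSpec:
    sequence: str = "AAAAAAAAAAAA"       # 1-letter amino acids (chain A)
    sequence_b: str = ""                 # second protein chain, if any
    nucleotide: str = ""                 # single RNA base (A/C/G/U), if any
    phi: float = IDEAL_HELIX[0]
    psi: float = IDEAL_HELIX[1]
    omega: float = IDEAL_HELIX[2]
    contacts: tuple[EngineeredContact, ...] = ()
    chain_gap: float = 25.0              # initial separation before placement
    jitter_sigma: float = 0.0            # optional seeded coordinate noise, A
    seed: int = 0
    start_number: int = 1


DEFAULT_CHI = {1: (180.0,), 2: (180.0, 90.0), 3: (180.0, 180.0, 90.0),
               4: (180.0, 180.0, 180.0, 180.0)}


def _default_chis(res3: str) -> tuple[float, ...]:
    n = N_CHI[res3]
    if n == 0:
        return ()
    if res3 in ("PHE", "TYR", "TRP", "HIS", "ASP", "ASN"):
        return DEFAULT_CHI[2][:n] if n >= 2 else (180.0,)
    return (180.0,) * n


def _protein_chain(sequence: str, chain_id: str, entity: str, phi: float,
                   psi: float, omega: float, start_number: int = 1) -> Chain:
    seq3 = []
    for letter in sequence:
        if letter.upper() not in AA_1TO3:
            raise FixtureConstructionError(
                f"not a protein 1-letter code: {letter!r}")
        seq3.append(AA_1TO3[letter.upper()])
    bb = build_backbone(len(seq3), phi, psi, omega)
    residues = []
    for i, (res3, coords) in enumerate(zip(seq3, bb)):
        atoms = [Atom(nm, "", coords[nm]) for nm in ("N", "CA", "C", "O")]
        side = build_sidechain(res3, coords["N"], coords["CA"], coords["C"],
                               _default_chis(res3))
        atoms += [Atom(nm, "", pos) for nm, pos in side.items()]
        residues.append(Residue(name=res3, auth_number=start_number + i,
                                atoms=atoms))
    return Chain(id=chain_id, residues=residues, entity_label=entity)


def _apply_jitter(model: StructureModel, sigma: float, seed: int) -> None:
    rng = np.random.default_rng(seed)
    for _c, _r, atom in model.iter_atoms():
        atom.pos = atom.pos + rng.normal(0.0, sigma, size=3)


def validate_fixture(model: StructureModel,
                     engineered: tuple[EngineeredContact, ...] = ()) -> None:
    """Raise if any two non-bonded heavy atoms sit closer than 1.8 A
    (engineered pairs excepted)."""
    from scipy.spatial import cKDTree
    sites = [(c.id, r.auth_number, a.name, a.pos)
             for c, r, a in model.iter_atoms(heavy_only=True)]
    allowed = {((ec.residue_a, ec.atom_a), (ec.residue_b, ec.atom_b))
               for ec in engineered}
    pos = np.array([s[3] for s in sites])
    tree = cKDTree(pos)
    for i, j in tree.query_pairs(1.8):
        ci, ri, ni, _ = sites[i]
        cj, rj, nj, _ = sites[j]
        # bonded geometry lives within a residue or across the peptide bond
        same_res = (ci, ri) == (cj, rj)
        adjacent = ci == cj and abs(ri - rj) == 1
        pairkey = ((ri, ni), (rj, nj))
        if same_res or adjacent or pairkey in allowed or pairkey[::-1] in allowed:
            continue
        d = float(np.linalg.norm(pos[i] - pos[j]))
        raise FixtureConstructionError(
            f"fixture atoms {ci}/{ri}/{ni} and {cj}/{rj}/{nj} at {d:.2f} A")


def make_ideal_helix(spec: FixtureSpec = FixtureSpec()) -> StructureModel:
    """Single protein chain built at the spec's backbone dihedrals.

    At the ideal alpha-helical dihedrals (-57, -47) the backbone carbonyl
    O(i) sits ~3.1 A from the amide N(i+4), the classic helical
    hydrogen-bond ladder.
    """
    if len(spec.sequence) < 1:
        raise FixtureConstructionError("sequence must be non-empty")
    chain = _protein_chain(spec.sequence, "A", "PROT1", spec.phi, spec.psi,
                           spec.omega, spec.start_number)
    model = StructureModel(id="ideal-helix", chains=[chain],
                           provenance=Provenance(source="synthetic", format="none"))
    if spec.jitter_sigma > 0:
        _apply_jitter(model, spec.jitter_sigma, spec.seed)
    return model


def _rigid_place_chain_b(model: StructureModel,
                         contacts: tuple[EngineeredContact, ...],
                         max_other_polar: float = 4.0) -> None:
    """Rigid-body transform of chain B so each engineered pair sits at its
    target distance, pointing chain B away from chain A; raises if the
    placement cannot avoid spurious inter-chain polar contacts."""
    chain_a = model.chain("A")
    chain_b = model.chain("B")
    a_coords = np.array([a.pos for _c, _r, a in model.iter_atoms(heavy_only=True)
                         if _c.id == "A"])
    centroid_a = a_coords.mean(axis=0)

    anchors, b_atoms, targets = [], [], []
    for ec in contacts:
        res_a = chain_a.residue(ec.residue_a)
        pa = res_a.atom(ec.atom_a).pos
        # extend along the anchor atom's own bond (roughly where its hydrogen
        # or lone pair points), so sibling atoms stay clear of the target
        parent_a = min((a for a in res_a.atoms
                        if a.name != ec.atom_a and not a.is_hydrogen),
                       key=lambda a: float(np.linalg.norm(a.pos - pa)))
        u = pa - parent_a.pos
        if np.linalg.norm(u) < 1e-6:
            u = pa - centroid_a
        u = u / np.linalg.norm(u)
        anchors.append((pa, u))
        b_atoms.append(chain_b.residue(ec.residue_b).atom(ec.atom_b))
        targets.append(pa + ec.distance * u)
    targets = np.array(targets)

    def apply(r: np.ndarray, t: np.ndarray) -> None:
        for res in chain_b.residues:
            for atom in res.atoms:
                atom.pos = r @ atom.pos + t

    b_centroid = np.array([a.pos for _c, _r, a in model.iter_atoms(heavy_only=True)
                           if _c.id == "B"]).mean(axis=0)
    if len(contacts) == 1:
        pa, u = anchors[0]
        atom_b = b_atoms[0]
        # orient chain B with its bulk behind the contact atom (away from
        # chain A), then sweep tilt and roll until the placement is free of
        # spurious inter-chain polar contacts
        parent = min((a for res in chain_b.residues for a in res.atoms
                      if a is not atom_b and not a.is_hydrogen),
                     key=lambda a: float(np.linalg.norm(a.pos - atom_b.pos)))
        bases = [geometry.rotation_aligning(atom_b.pos - parent.pos, -u),
                 geometry.rotation_aligning(b_centroid - atom_b.pos, u)]
        w = np.cross(u, [1.0, 0.0, 0.0])
        if np.linalg.norm(w) < 1e-6:
            w = np.cross(u, [0.0, 1.0, 0.0])
        w /= np.linalg.norm(w)
        saved = [(a, a.pos.copy()) for res in chain_b.residues for a in res.atoms]
        for r0 in bases:
            for tilt in (0.0, 20.0, -20.0, 40.0, -40.0):
                rt = geometry.rotation_about(w, tilt) @ r0
                for roll in range(0, 360, 30):
                    r = geometry.rotation_about(u, float(roll)) @ rt
                    t = targets[0] - r @ atom_b.pos
                    apply(r, t)
                    if _placement_ok(model, contacts, max_other_polar):
                        return
                    for a, p in saved:
                        a.pos = p.copy()
        raise FixtureConstructionError(
            "cannot place chain B without spurious inter-chain polar contacts")
    # several simultaneous constraints: least-squares rigid fit
    mobile = np.array([a.pos for a in b_atoms])
    r, t = geometry.kabsch(mobile, targets)
    apply(r, t)
    realized = np.array([a.pos for a in b_atoms])
    if np.max(np.abs(np.linalg.norm(realized - np.array([a for a, _u in anchors]),
                                    axis=1)
                     - np.array([ec.distance for ec in contacts]))) > 0.01:
        raise FixtureConstructionError(
            "engineered contact set is not rigidly satisfiable to 0.01 A")
    if not _placement_ok(model, contacts, max_other_polar):
        raise FixtureConstructionError(
            "cannot place chain B without spurious inter-chain polar contacts")


def _placement_ok(model: StructureModel, contacts: tuple[EngineeredContact, ...],
                  max_other_polar: float) -> bool:
    from .chemistry import NONE, polar_role
    engineered = {((ec.residue_a, ec.atom_a), (ec.residue_b, ec.atom_b))
                  for ec in contacts}
    a_sites = [(r.auth_number, a.name, a.pos, r.name)
               for c, r, a in model.iter_atoms(heavy_only=True) if c.id == "A"]
    b_sites = [(r.auth_number, a.name, a.pos, r.name)
               for c, r, a in model.iter_atoms(heavy_only=True) if c.id != "A"]
    for ra, na, pa, rna in a_sites:
        for rb, nb, pb, rnb in b_sites:
            d = float(np.linalg.norm(pa - pb))
            if d < 1.8:
                return False
            if d >= max_other_polar:
                continue
            if ((ra, na), (rb, nb)) in engineered:
                continue
            if polar_role(rna, na) != NONE and polar_role(rnb, nb) != NONE:
                return False
    return True


def make_engineered_pair_fixture(spec: FixtureSpec) -> StructureModel:
    """Two protein chains with engineered donor-acceptor pairs at exact
    distances and no other inter-chain polar contact within 4 A."""
    if not spec.contacts:
        raise FixtureConstructionError("spec.contacts must be non-empty")
    if not spec.sequence_b:
        raise FixtureConstructionError("spec.sequence_b must be set")
    chain_a = _protein_chain(spec.sequence, "A", "PROT1", spec.phi, spec.psi,
                             spec.omega, spec.start_number)
    chain_b = _protein_chain(spec.sequence_b, "B", "PROT2", spec.phi, spec.psi,
                             spec.omega, spec.start_number)
    for res in chain_b.residues:       # park B away before rigid placement
        for atom in res.atoms:
            atom.pos = atom.pos + np.array([spec.chain_gap, 0.0, 0.0])
    model = StructureModel(id="engineered-pair", chains=[chain_a, chain_b],
                           provenance=Provenance(source="synthetic", format="none"))
    _rigid_place_chain_b(model, spec.contacts)
    for ec in spec.contacts:           # verify the realized distances
        pa = model.chain("A").residue(ec.residue_a).atom(ec.atom_a).pos
        pb = model.chain("B").residue(ec.residue_b).atom(ec.atom_b).pos
        realized = float(np.linalg.norm(pa - pb))
        if abs(realized - ec.distance) > 0.01:
            raise FixtureConstructionError(
                f"engineered distance {realized:.3f} != {ec.distance:.3f}")
    validate_fixture(model, spec.contacts)
    if spec.jitter_sigma > 0:
        _apply_jitter(model, spec.jitter_sigma, spec.seed)
    return model


# --------------------------------------------------------------------------
# Synthetic ribonucleotide (idealized geometry, C3'-endo-like ribose)

_PYRIMIDINE_BASE = [
    # name, refs, bond, angle, torsion (chi measured O4'-C1'-N1-C2 ~ -160, anti)
    ("N1", ("C2'", "O4'", "C1'"), 1.468, 108.5, 120.0),
    ("C2", ("O4'", "C1'", "N1"), 1.381, 118.0, -160.0),
    ("O2", ("C1'", "N1", "C2"), 1.219, 122.9, 0.0),
    ("N3", ("C1'", "N1", "C2"), 1.373, 114.9, 180.0),
    ("C4", ("N1", "C2", "N3"), 1.380, 127.0, 0.0),
    ("C5", ("C2", "N3", "C4"), 1.440, 114.6, 0.0),
    ("C6", ("N3", "C4", "C5"), 1.338, 119.7, 0.0),
]
_PYRIMIDINE_EXO = {
    "U": ("O4", ("C2", "N3", "C4"), 1.232, 119.4, 180.0),
    "C": ("N4", ("C2", "N3", "C4"), 1.337, 118.0, 180.0),
}
_PURINE_BASE = [
    ("N9", ("C2'", "O4'", "C1'"), 1.468, 108.3, 120.0),
    ("C4", ("O4'", "C1'", "N9"), 1.374, 126.5, -160.0),
    ("C8", ("O4'", "C1'", "N9"), 1.371, 127.7, 20.0),
    ("N3", ("C8", "N9", "C4"), 1.342, 127.0, 180.0),
    ("C5", ("C8", "N9", "C4"), 1.382, 106.0, 0.0),
    ("N7", ("N9", "C4", "C5"), 1.387, 110.7, 0.0),
    ("C6", ("N9", "C4", "C5"), 1.409, 117.0, 180.0),
    ("N1", ("C4", "C5", "C6"), 1.349, 117.7, 0.0),
    ("C2", ("C5", "C6", "N1"), 1.331, 118.6, 0.0),
]
_PURINE_EXO = {
    "A": [("N6", ("C4", "C5", "C6"), 1.335, 123.5, 180.0)],
    "G": [("O6", ("C4", "C5", "C6"), 1.237, 128.4, 180.0),
          ("N2", ("C6", "N1", "C2"), 1.341, 116.2, 180.0)],
}
_SUGAR_PHOSPHATE = [
    ("C3'", None, 1.525, 101.3, 57.0),  # placed from dummy; see builder
    ("C4'", ("C1'", "C2'", "C3'"), 1.523, 102.6, 37.5),
    ("O4'", ("C2'", "C3'", "C4'"), 1.451, 104.0, -35.8),
    ("O2'", ("O4'", "C1'", "C2'"), 1.413, 110.6, -146.5),
    ("O3'", ("C4'", "C2'", "C3'"), 1.423, 111.0, 120.0),
    ("C5'", ("O4'", "C3'", "C4'"), 1.508, 115.5, -120.0),
    ("O5'", ("C3'", "C4'", "C5'"), 1.440, 110.2, 54.0),
    ("P", ("C4'", "C5'", "O5'"), 1.593, 120.9, 180.0),
    ("OP1", ("C5'", "O5'", "P"), 1.485, 108.1, 60.0),
    ("OP2", ("C5'", "O5'", "P"), 1.485, 108.1, 180.0),
    ("OP3", ("C5'", "O5'", "P"), 1.581, 104.0, -60.0),
]


def build_nucleotide(base: str = "U") -> dict[str, np.ndarray]:
    """Idealized 5'-phosphate ribonucleotide coordinates (heavy atoms)."""
    base = base.upper()
    if base not in RNA_RESNAMES or base == "I":
        raise FixtureConstructionError(f"unsupported RNA base {base!r}")
    c: dict[str, np.ndarray] = {
        "C1'": np.zeros(3),
        "C2'": np.array([1.528, 0.0, 0.0]),
    }
    dummy = np.array([0.0, 1.0, 0.0])
    for name, refs, bond, angle, torsion in _SUGAR_PHOSPHATE:
        a, b, cc = (dummy, c["C1'"], c["C2'"]) if refs is None else (c[refs[0]], c[refs[1]], c[refs[2]])
        c[name] = geometry.place_atom(a, b, cc, bond, angle, torsion)
    entries = list(_PYRIMIDINE_BASE) if base in ("U", "C") else list(_PURINE_BASE)
    if base in ("U", "C"):
        entries.append(_PYRIMIDINE_EXO[base])
    else:
        entries += _PURINE_EXO[base]
    for name, refs, bond, angle, torsion in entries:
        c[name] = geometry.place_atom(c[refs[0]], c[refs[1]], c[refs[2]],
                                      bond, angle, torsion)
    return c


def make_protein_rna_fixture(spec: FixtureSpec) -> StructureModel:
    """Protein chain plus a single posed ribonucleotide with one engineered
    polar contact (partner entity "RNA1")."""
    if not spec.nucleotide:
        raise FixtureConstructionError("spec.nucleotide must be set")
    if len(spec.contacts) != 1:
        raise FixtureConstructionError(
            "protein-RNA fixture takes exactly one engineered contact")
    chain_a = _protein_chain(spec.sequence, "A", "PROT1", spec.phi, spec.psi,
                             spec.omega, spec.start_number)
    coords = build_nucleotide(spec.nucleotide)
    atoms = [Atom(nm, "", pos + np.array([spec.chain_gap, 0.0, 0.0]))
             for nm, pos in coords.items()]
    nuc = Residue(name=spec.nucleotide.upper(), auth_number=1, atoms=atoms)
    chain_r = Chain(id="R", residues=[nuc], entity_label="RNA1")
    model = StructureModel(id="protein-rna", chains=[chain_a, chain_r],
                           provenance=Provenance(source="synthetic", format="none"))
    ec = spec.contacts[0]
    # reuse the rigid placement with the RNA chain standing in for chain B
    chain_r.id = "B"
    try:
        _rigid_place_chain_b(model, spec.contacts)
    finally:
        chain_r.id = "R"
    realized = float(np.linalg.norm(
        model.chain("A").residue(ec.residue_a).atom(ec.atom_a).pos
        - chain_r.residues[0].atom(ec.atom_b).pos))
    if abs(realized - ec.distance) > 0.01:
        raise FixtureConstructionError(
            f"engineered distance {realized:.3f} != {ec.distance:.3f}")
    validate_fixture(model, spec.contacts)
    if spec.jitter_sigma > 0:
        _apply_jitter(model, spec.jitter_sigma, spec.seed)
    return model
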