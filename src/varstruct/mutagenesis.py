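"""In-silico point mutagenesis: replace one side chain with an
idealized-geometry model of the variant residue.

The backbone is never moved. The variant side chain is grown from the
z-matrix template on the existing N/CA/C frame, and the rotamer is chosen as
the candidate with the fewest steric clashes over a deterministic coarse chi
grid; ties are broken by staying closest to the observed wild-type chi1 and
then by grid order. No energy model, no relaxation: at the 3-4 A resolution
of the structures this targets, a clash-free idealized rotamer is the level
of detail the distance-banded contact analysis downstream can support.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .build import build_sidechain, measure_chis
from .chemistry import (AA_1TO3, CANONICAL_AA3, N_CHI,
                        TERMINAL_FLIP_RESIDUES)
from .model import Atom, StructureModel, StructureError

CHI_GRID = (180.0, -60.0, 60.0)           # searched in this order
FLIP_EXTENSION = (0.0, -120.0, 120.0)     # extra terminal-amide/carboxyl flips


class MutagenesisError(StructureError):
    pass


class ReferenceMismatchError(MutagenesisError):
    pass


class IncompleteBackboneError(MutagenesisError):
    pass


class UnmodelledResidueError(MutagenesisError):
    pass


@dataclass(frozen=True)
class MutationConfig:
    clash_cutoff: float = 2.5      # heavy-atom pair closer than this clashes
    allow_ref_mismatch: bool = False
    seed_wt_chis: bool = True      # add observed chis as a candidate rotamer


DEFAULT_MUTATION_CONFIG = MutationConfig()


@dataclass
class RotamerPlacement:
    res_name: str
    chain_id: str
    res_number: int
    icode: str
    chis: tuple[float, ...]
    coords: dict[str, np.ndarray]   # side-chain atom name -> position
    clash_count: int = -1
    selected: bool = False


@dataclass
class MutantModel:
    """A structure with exactly one residue's side chain replaced."""
    model: StructureModel
    chain_id: str
    res_number: int
    icode: str
    ref_aa: str
    alt_aa: str
    chis: tuple[float, ...]
    clash_count: int
    notes: tuple[str, ...] = ()


def candidate_chi_sets(alt_aa3: str) -> list[tuple[float, ...]]:
    """Deterministic rotamer grid for a residue type, in search order."""
    n = N_CHI[alt_aa3]
    if n == 0:
        return [()]
    grids = [CHI_GRID] * n
    if alt_aa3 in TERMINAL_FLIP_RESIDUES:
        grids[-1] = CHI_GRID + FLIP_EXTENSION
    return list(itertools.product(*grids))


def clash_score(placement: RotamerPlacement, environment: StructureModel,
                config: MutationConfig = DEFAULT_MUTATION_CONFIG) -> int:
    """Count of (placed side-chain atom, environment heavy atom) pairs closer
    than the clash cutoff.

    The mutated residue's own atoms are excluded, as are the covalently
    adjacent backbone atoms of the flanking residues (C of the preceding and
    N of the following residue), whose proximity to CB is bonded geometry,
    not a clash.
    """
    placed = list(placement.coords.items())
    if not placed:
        return 0
    target = (placement.chain_id, placement.res_number, placement.icode)
    env_sites = []
    for chain, res, atom in environment.iter_atoms(heavy_only=True,
                                                   include_waters=False):
        if (chain.id, res.auth_number, res.icode) == target:
            continue
        if chain.id == target[0] and res.auth_number == target[1] - 1 and atom.name == "C":
            continue
        if chain.id == target[0] and res.auth_number == target[1] + 1 and atom.name == "N":
            continue
        env_sites.append(atom.pos)
    if not env_sites:
        return 0
    tree = cKDTree(np.array(env_sites))
    count = 0
    for _name, pos in placed:
        hits = tree.query_ball_point(pos, config.clash_cutoff)
        count += sum(1 for j in hits
                     if float(np.linalg.norm(np.array(env_sites[j]) - pos))
                     < config.clash_cutoff)
    return count


def _angular_gap(a: float, b: float) -> float:
    d = abs(a - b) % 360.0
    return min(d, 360.0 - d)


def enumerate_rotamers(model: StructureModel, chain_id: str, position: int,
                       alt_aa3: str, icode: str = "",
                       config: MutationConfig = DEFAULT_MUTATION_CONFIG,
                       wt_chis: tuple[float, ...] = (),
                       ) -> list[RotamerPlacement]:
    """Realize every candidate rotamer of ``alt_aa3`` on the target backbone
    and score it; the selected placement is flagged.

    Candidate order is fixed (grid order, wild-type seed first when present),
    so selection is deterministic.
    """
    res = model.chain(chain_id).residue(position, icode)
    n = res.atom("N").pos
    ca = res.atom("CA").pos
    c = res.atom("C").pos
    candidates = candidate_chi_sets(alt_aa3)
    if config.seed_wt_chis and len(wt_chis) == N_CHI[alt_aa3] and wt_chis:
        candidates = [tuple(wt_chis)] + candidates
    placements = []
    for chis in candidates:
        coords = build_sidechain(alt_aa3, n, ca, c, chis)
        p = RotamerPlacement(alt_aa3, chain_id, position, icode, chis, coords)
        p.clash_count = clash_score(p, model, config)
        placements.append(p)
    wt_chi1 = wt_chis[0] if wt_chis else None

    def rank(idx_p):
        idx, p = idx_p
        tie = _angular_gap(p.chis[0], wt_chi1) if (wt_chi1 is not None and p.chis) else 0.0
        return (p.clash_count, tie, idx)

    best_idx, best = min(enumerate(placements), key=rank)
    best.selected = True
    return placements


def mutate_residue(model: StructureModel, chain_id: str, position: int,
                   alt_aa: str, icode: str = "", expected_ref: str = "",
                   config: MutationConfig = DEFAULT_MUTATION_CONFIG,
                   ) -> MutantModel:
    """Replace the side chain of one residue with the variant amino acid.

    The rebuilt residue keeps its backbone atoms bitwise unchanged; all other
    residues are untouched. ``expected_ref`` (1- or 3-letter), when given, is
    checked against the observed residue name.
    """
    alt3 = AA_1TO3.get(alt_aa.upper(), alt_aa.upper())
    if alt3 not in CANONICAL_AA3:
        raise MutagenesisError(f"not a canonical amino acid: {alt_aa!r}")
    chain = model.chain(chain_id)
    try:
        res = chain.residue(position, icode)
    except StructureError as exc:
        raise UnmodelledResidueError(
            f"position {position}{icode} is not present in chain {chain_id} "
            f"(unresolved or out of range)") from exc
    if not res.is_amino_acid():
        raise MutagenesisError(f"residue {res.label()} is not a protein residue")
    if not res.has_complete_backbone:
        raise IncompleteBackboneError(f"residue {res.label()} lacks N/CA/C")
    if expected_ref:
        ref3 = AA_1TO3.get(expected_ref.upper(), expected_ref.upper())
        if ref3 != res.name:
            msg = (f"reference mismatch at {chain_id}/{position}{icode}: "
                   f"model has {res.name}, variant expects {ref3}")
            if not config.allow_ref_mismatch:
                raise ReferenceMismatchError(msg)

    wt_chis = measure_chis(res) if res.name == alt3 else ()
    placements = enumerate_rotamers(model, chain_id, position, alt3, icode,
                                    config, wt_chis)
    best = next(p for p in placements if p.selected)

    mutant = model.copy()
    mres = mutant.chain(chain_id).residue(position, icode)
    backbone = [a for a in mres.atoms if a.name in ("N", "CA", "C", "O", "OXT")]
    side = [Atom(name=nm, element="", pos=np.array(pos))
            for nm, pos in best.coords.items()]
    mres.atoms = backbone + side
    mres.name = alt3

    notes = []
    if alt3 == "PRO":
        notes.append("proline introduced: backbone strain (new kink) is not "
                     "modeled; the fixed-pucker ring is placed on the "
                     "unchanged backbone")
    return MutantModel(model=mutant, chain_id=chain_id, res_number=position,
                       icode=icode, ref_aa=res.name, alt_aa=alt3,
                       chis=best.chis, clash_count=best.clash_count,
                       notes=tuple(notes))
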