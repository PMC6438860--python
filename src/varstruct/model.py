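"""In-memory structure model: chains of residues of atoms, Angstrom coords.

The model keeps exactly one coordinate set (one "model" in PDB terms) and
author residue numbering, which is what positions quoted in the clinical and
structural literature refer to.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np

from .chemistry import (CANONICAL_AA3, DNA_RESNAMES, RNA_RESNAMES,
                        WATER_RESNAMES, element_of)

PROTEIN, RNA, OTHER = "protein", "rna", "other"


class StructureError(Exception):
    """Base class for structure-model errors."""


class UnknownChainError(StructureError):
    pass


class UnknownResidueError(StructureError):
    pass


class EmptyStructureError(StructureError):
    pass


@dataclass
class Atom:
    name: str
    element: str
    pos: np.ndarray                # shape (3,), Angstrom
    occupancy: float = 1.0
    altloc: str = ""
    is_hydrogen: bool = False

    def __post_init__(self):
        self.pos = np.asarray(self.pos, dtype=float)
        if self.pos.shape != (3,) or not np.all(np.isfinite(self.pos)):
            raise ValueError(f"atom {self.name}: position must be a finite 3-vector")
        if not (0.0 <= self.occupancy <= 1.0):
            raise ValueError(f"atom {self.name}: occupancy {self.occupancy} outside [0, 1]")
        if not self.element:
            self.element = element_of(self.name)
        self.is_hydrogen = self.is_hydrogen or self.element in ("H", "D")


@dataclass
class Residue:
    name: str                      # 3-letter protein / 1-2 letter nucleotide code
    auth_number: int
    icode: str = ""
    atoms: list[Atom] = field(default_factory=list)
    label_number: Optional[int] = None
    is_water: bool = False
    is_polymer: bool = True

    def __post_init__(self):
        self.name = self.name.strip()
        if self.name in WATER_RESNAMES:
            self.is_water = True
            self.is_polymer = False

    @property
    def key(self) -> tuple[int, str]:
        return (self.auth_number, self.icode)

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"residue {self.name}{self.auth_number}{self.icode}: no atom {name!r}")

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]

    @property
    def has_complete_backbone(self) -> bool:
        return all(self.has_atom(n) for n in ("N", "CA", "C"))

    def is_amino_acid(self) -> bool:
        return self.name in CANONICAL_AA3

    def label(self) -> str:
        return f"{self.name}{self.auth_number}{self.icode}"


@dataclass
class Chain:
    id: str
    residues: list[Residue] = field(default_factory=list)
    entity_label: str = ""

    @property
    def polymer_type(self) -> str:
        counts = {PROTEIN: 0, RNA: 0, OTHER: 0}
        for r in self.residues:
            if not r.is_polymer:
                continue
            if r.name in CANONICAL_AA3:
                counts[PROTEIN] += 1
            elif r.name in RNA_RESNAMES:
                counts[RNA] += 1
            elif r.name in DNA_RESNAMES:
                counts[OTHER] += 1
            else:
                counts[OTHER] += 1
        if not any(counts.values()):
            return OTHER
        return max(counts, key=counts.get)

    def residue(self, auth_number: int, icode: str = "") -> Residue:
        for r in self.residues:
            if r.auth_number == auth_number and r.icode == icode:
                return r
        nearest = sorted(self.residues, key=lambda r: abs(r.auth_number - auth_number))[:3]
        hint = ", ".join(r.label() for r in nearest)
        raise UnknownResidueError(
            f"chain {self.id}: no residue {auth_number}{icode!r}; nearest: {hint}")

    def sort_residues(self) -> None:
        self.residues.sort(key=lambda r: (r.auth_number, r.icode))


@dataclass
class Provenance:
    source: str = "in-memory"
    format: str = "none"
    model_index: int = 1


@dataclass
class StructureModel:
    id: str
    chains: list[Chain] = field(default_factory=list)
    provenance: Provenance = field(default_factory=Provenance)

    def __post_init__(self):
        ids = [c.id for c in self.chains]
        if len(ids) != len(set(ids)):
            raise StructureError(f"duplicate chain ids in structure {self.id}: {ids}")

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.id == chain_id:
                return c
        raise UnknownChainError(
            f"structure {self.id}: no chain {chain_id!r} (have {[c.id for c in self.chains]})")

    def has_chain(self, chain_id: str) -> bool:
        return any(c.id == chain_id for c in self.chains)

    def iter_atoms(self, heavy_only: bool = False, include_waters: bool = True,
                   ) -> Iterator[tuple[Chain, Residue, Atom]]:
        for c in self.chains:
            for r in c.residues:
                if r.is_water and not include_waters:
                    continue
                for a in r.atoms:
                    if heavy_only and a.is_hydrogen:
                        continue
                    yield c, r, a

    def entity_of(self, chain_id: str) -> str:
        c = self.chain(chain_id)
        return c.entity_label or c.id

    def copy(self) -> "StructureModel":
        return copy.deepcopy(self)

    def apply_entity_map(self, mapping: dict[str, str]) -> None:
        """Assign molecule names (entity labels) to chains by chain id."""
        for c in self.chains:
            if c.id in mapping:
                c.entity_label = mapping[c.id]


def models_equal(a: StructureModel, b: StructureModel, tol: float = 1e-3) -> bool:
    """Structural equality: same chain/residue/atom identity, coords to tol."""
    if len(a.chains) != len(b.chains):
        return False
    for ca, cb in zip(a.chains, b.chains):
        if ca.id != cb.id or len(ca.residues) != len(cb.residues):
            return False
        for ra, rb in zip(ca.residues, cb.residues):
            if (ra.name, ra.key) != (rb.name, rb.key) or len(ra.atoms) != len(rb.atoms):
                return False
            for aa, ab in zip(ra.atoms, rb.atoms):
                if aa.name != ab.name:
                    return False
                if np.max(np.abs(aa.pos - ab.pos)) > tol:
                    return False
    return True
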