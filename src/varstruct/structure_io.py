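"""Read and write macromolecular structures (PDB / mmCIF) into the uniform
chain-residue-atom model.

Conventions, chosen to match how variant positions are cited in the
literature:

* author residue numbering (``auth_seq_id``) is authoritative for lookup;
  ``label_seq_id`` is retained but never used to address residues;
* only the first coordinate model of a multi-model file is kept (discarded
  models are logged);
* alternate-location groups are collapsed to the highest-occupancy conformer,
  ties broken by lexicographically first altloc id;
* hydrogens and waters are retained in the model but flagged, so that
  downstream geometry can exclude them.

Parsing and serialization are delegated to gemmi.
"""

from __future__ import annotations

import logging
import os
from collections import defaultdict

import gemmi

from .model import (Atom, Chain, EmptyStructureError, Provenance, Residue,
                    StructureModel, StructureError)

logger = logging.getLogger(__name__)

_FORMATS = {"pdb", "mmcif", "auto"}


class ParseError(StructureError):
    pass


class FormatError(StructureError):
    pass


def _coor_format(fmt: str) -> gemmi.CoorFormat:
    return {"pdb": gemmi.CoorFormat.Pdb,
            "mmcif": gemmi.CoorFormat.Mmcif,
            "auto": gemmi.CoorFormat.Detect}[fmt]


def _collapse_altlocs(res: gemmi.Residue) -> list[gemmi.Atom]:
    """Keep one conformer per atom name: highest occupancy, ties by altloc id."""
    groups: dict[str, list[gemmi.Atom]] = defaultdict(list)
    for at in res:
        groups[at.name].append(at)
    kept = []
    for name, alts in groups.items():
        best = min(alts, key=lambda a: (-a.occ, _altloc_str(a)))
        kept.append(best)
    return kept


def _altloc_str(atom: gemmi.Atom) -> str:
    al = atom.altloc
    return "" if al in ("\x00", " ", "") else al


def parse_structure(path: str, format: str = "auto") -> StructureModel:
    """Parse a PDB or mmCIF file into a :class:`StructureModel`.

    Only the first coordinate model is retained; altloc groups are collapsed
    to the highest-occupancy conformer (ties -> lexicographically first
    altloc id). Waters and hydrogens are kept but flagged.
    """
    if format not in _FORMATS:
        raise ValueError(f"unknown format {format!r}; expected one of {sorted(_FORMATS)}")
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        st = gemmi.read_structure(str(path), format=_coor_format(format))
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise EmptyStructureError(f"{path}: no coordinate models")
    if len(st) > 1:
        logger.warning("%s: keeping model 1 of %d; discarding %d further model(s)",
                       path, len(st), len(st) - 1)
    st.setup_entities()
    gmodel = st[0]

    fmt = format
    if fmt == "auto":
        fmt = "mmcif" if str(path).lower().endswith((".cif", ".mmcif")) else "pdb"

    chains = []
    n_polymer_res = 0
    for gchain in gmodel:
        residues = []
        for gres in gchain:
            icode = gres.seqid.icode.strip()
            atoms = []
            for gat in _collapse_altlocs(gres):
                atoms.append(Atom(
                    name=gat.name,
                    element=gat.element.name,
                    pos=(gat.pos.x, gat.pos.y, gat.pos.z),
                    occupancy=min(max(gat.occ, 0.0), 1.0),
                    altloc=_altloc_str(gat),
                    is_hydrogen=gat.is_hydrogen(),
                ))
            res = Residue(
                name=gres.name,
                auth_number=gres.seqid.num,
                icode=icode,
                atoms=atoms,
                label_number=gres.label_seq,
            )
            if gres.is_water():
                res.is_water = True
                res.is_polymer = False
            elif gres.het_flag == "H" and not res.is_amino_acid() \
                    and res.name not in ("A", "U", "G", "C"):
                res.is_polymer = False
            if res.is_polymer:
                n_polymer_res += 1
            residues.append(res)
        chain = Chain(id=gchain.name, residues=residues)
        chain.sort_residues()
        chains.append(chain)

    if n_polymer_res == 0:
        raise EmptyStructureError(f"{path}: no polymer chains")

    sid = st.name.strip() or os.path.splitext(os.path.basename(path))[0]
    return StructureModel(id=sid, chains=chains,
                          provenance=Provenance(source=str(path), format=fmt, model_index=1))


def _to_gemmi(model: StructureModel, strict_pdb: bool) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = model.id
    gm = gemmi.Model("1")
    for chain in model.chains:
        if strict_pdb and len(chain.id) > 1:
            raise FormatError(
                f"chain id {chain.id!r} does not fit the single-character PDB field")
        gc = gemmi.Chain(chain.id)
        for res in chain.residues:
            gr = gemmi.Residue()
            gr.name = res.name
            gr.seqid = gemmi.SeqId(res.auth_number, res.icode or " ")
            for atom in res.atoms:
                if strict_pdb and len(atom.name) > 4:
                    raise FormatError(
                        f"atom name {atom.name!r} exceeds the 4-character PDB field")
                ga = gemmi.Atom()
                ga.name = atom.name
                ga.element = gemmi.Element(atom.element or "X")
                ga.pos = gemmi.Position(*atom.pos)
                ga.occ = atom.occupancy
                if atom.altloc:
                    ga.altloc = atom.altloc
                gr.add_atom(ga)
            gc.add_residue(gr)
        gm.add_chain(gc)
    st.add_model(gm)
    st.setup_entities()
    return st


def write_structure(model: StructureModel, path: str, format: str) -> None:
    """Write a model as PDB or mmCIF.

    Coordinates survive a round-trip to within the format precision
    (0.001 A). Raises :class:`FormatError` if an identifier does not fit the
    stricter PDB fields.
    """
    if format not in ("pdb", "mmcif"):
        raise ValueError(f"unknown format {format!r}; expected 'pdb' or 'mmcif'")
    if not model.chains or all(not c.residues for c in model.chains):
        raise EmptyStructureError("refusing to write an empty model")
    st = _to_gemmi(model, strict_pdb=(format == "pdb"))
    if format == "pdb":
        st.write_pdb(str(path))
    else:
        st.make_mmcif_document().write_file(str(path))


def select_residue(model: StructureModel, chain_id: str, auth_number: int,
                   icode: str = "") -> Residue:
    """Return the unique residue addressed by (chain, author number, icode)."""
    return model.chain(chain_id).residue(auth_number, icode)
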