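"""Polar-interaction analysis: contact shells, hydrogen-bond detection and
distance banding, and wild-type vs mutant interaction diffing.

The hydrogen-bond criterion is deliberately distance-only on heavy atoms:
donor-acceptor separations of 2.2-2.5 A are classed strong, 2.5-3.2 A
moderate, 3.2-4.0 A weak. Cryo-EM models at 3-4 A resolution carry no
hydrogens, so an explicit-hydrogen or angle-resolved criterion would rest on
inferred positions; an optional donor-angle filter exists but is off by
default. All searches are closed at the 4 A contact radius.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .chemistry import ACCEPTOR, BOTH, DONOR, NONE, SULFUR_ROLE_ATOMS, polar_role
from .model import Residue, StructureModel, StructureError

COVALENT_CUTOFF = 1.85  # heavy-atom pair closer than this is treated as bonded


class UnknownChemistryError(StructureError):
    pass


@dataclass(frozen=True)
class HBondBands:
    """Donor-acceptor distance bands (A); half-open on the left, closed top."""
    too_close: float = 2.2
    strong: float = 2.5
    moderate: float = 3.2
    weak: float = 4.0
    radius: float = 4.0

    def __post_init__(self):
        if not (self.too_close < self.strong < self.moderate < self.weak):
            raise ValueError("band edges must be strictly increasing")
        if self.radius < self.weak:
            raise ValueError("contact radius must cover the top band edge")


DEFAULT_BANDS = HBondBands()


@dataclass(frozen=True)
class ContactConfig:
    radius: float = 4.0
    include_waters: bool = False
    include_sulfur: bool = False
    donor_angle_filter: bool = False
    min_donor_angle: float = 90.0  # D-A-AA angle floor when filter enabled


DEFAULT_CONFIG = ContactConfig()


@dataclass(frozen=True)
class AtomSite:
    """An atom with enough identity for reporting and diffing."""
    chain_id: str
    res_name: str
    res_number: int
    icode: str
    atom_name: str
    entity: str
    pos: tuple[float, float, float]

    @property
    def residue_id(self) -> tuple[str, int, str]:
        return (self.chain_id, self.res_number, self.icode)

    def label(self) -> str:
        return f"{self.chain_id}/{self.res_name}{self.res_number}{self.icode}/{self.atom_name}"


@dataclass(frozen=True)
class PolarContact:
    atom: AtomSite          # atom of the query residue
    partner: AtomSite
    distance: float

    @property
    def same_chain(self) -> bool:
        return self.atom.chain_id == self.partner.chain_id

    @property
    def partner_entity(self) -> str:
        return self.partner.entity

    @property
    def key(self) -> tuple:
        """Diff key: partner residue identity + partner atom + own atom name."""
        return (self.partner.chain_id, self.partner.res_number,
                self.partner.icode, self.partner.res_name,
                self.partner.atom_name, self.atom.atom_name)


@dataclass(frozen=True)
class HBond(PolarContact):
    band: str = ""
    direction: str = "ambiguous"  # role of the query atom: donor/acceptor/ambiguous


@dataclass
class ContactDiff:
    """Gained/lost interactions between wild-type and mutant, keyed stably."""
    chain_id: str
    res_number: int
    icode: str = ""
    gained_hbonds: dict = field(default_factory=dict)   # key -> HBond (mutant side)
    lost_hbonds: dict = field(default_factory=dict)     # key -> HBond (wt side)
    gained_polar: dict = field(default_factory=dict)
    lost_polar: dict = field(default_factory=dict)

    @property
    def affects_hbond_within(self) -> str:
        changed = [h for h in (*self.gained_hbonds.values(), *self.lost_hbonds.values())
                   if h.same_chain]
        return "Y" if changed else "N"

    @property
    def affects_hbond_other(self) -> str:
        return "Y" if self.interchain_partners else "N"

    @property
    def interchain_partners(self) -> tuple[str, ...]:
        names = []
        for h in (*self.gained_hbonds.values(), *self.lost_hbonds.values()):
            if not h.same_chain and h.partner_entity not in names:
                names.append(h.partner_entity)
        return tuple(names)

    @property
    def affects_polar_contacts(self) -> str:
        """Y iff a polar contact was lost beyond those already counted as
        hydrogen-bond changes (the summary table keeps these separate)."""
        hbond_keys = set(self.gained_hbonds) | set(self.lost_hbonds)
        return "Y" if any(k not in hbond_keys for k in self.lost_polar) else "N"


@dataclass
class ResidueContacts:
    """Contact sets of one residue, the unit that gets diffed."""
    chain_id: str
    res_number: int
    icode: str
    res_name: str
    hbonds: list[HBond]
    polar: list[PolarContact]
    neighbor_count: int  # all heavy-atom neighbors in the shell, polar or not


# -------------------------------------------------------------------------

def _sites(model: StructureModel, include_waters: bool) -> list[AtomSite]:
    out = []
    for chain, res, atom in model.iter_atoms(heavy_only=True,
                                             include_waters=include_waters):
        out.append(AtomSite(chain.id, res.name, res.auth_number, res.icode,
                            atom.name, chain.entity_label or chain.id,
                            tuple(float(x) for x in atom.pos)))
    return out


def neighbors_within(model: StructureModel, query_atoms: list[AtomSite],
                     radius: float, config: ContactConfig = DEFAULT_CONFIG,
                     ) -> set[tuple[AtomSite, AtomSite, float]]:
    """All (query atom, environment atom, distance) heavy-atom pairs with
    d <= radius, excluding pairs internal to the query set.

    Accelerated with a k-d tree; exact (closed) radius comparison.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if not query_atoms:
        return set()
    env = _sites(model, config.include_waters)
    qset = set(query_atoms)
    env_pos = np.array([s.pos for s in env])
    tree = cKDTree(env_pos)
    result = set()
    for q in query_atoms:
        for j in tree.query_ball_point(q.pos, radius):
            e = env[j]
            if e in qset or e == q:
                continue
            d = float(np.linalg.norm(np.array(q.pos) - env_pos[j]))
            if d <= radius:
                result.add((q, e, d))
    return result


def classify_hbond_distance(d: float, bands: HBondBands = DEFAULT_BANDS) -> str:
    """Band label for a donor-acceptor distance (A).

    Bands are half-open on the left and closed at the top edge:
    [2.2, 2.5) strong, [2.5, 3.2) moderate, [3.2, 4.0] weak; below 2.2 is
    "too-close" (shorter than a credible hydrogen bond), above the contact
    radius "none".
    """
    if d <= 0:
        raise ValueError(f"distance must be positive, got {d}")
    if d < bands.too_close:
        return "too-close"
    if d < bands.strong:
        return "strong"
    if d < bands.moderate:
        return "moderate"
    if d <= bands.weak:
        return "weak"
    return "none"


def atom_polar_role(res_name: str, atom_name: str,
                    config: ContactConfig = DEFAULT_CONFIG) -> str:
    """Donor/acceptor role of an atom; sulfur roles only when configured."""
    if (res_name, atom_name) in SULFUR_ROLE_ATOMS and not config.include_sulfur:
        return NONE
    return polar_role(res_name, atom_name)


def _bonded_maps(sites: list[AtomSite]) -> tuple[dict, dict]:
    """1-2 and 1-3 adjacency (by site index) from a covalent distance cutoff."""
    pos = np.array([s.pos for s in sites])
    tree = cKDTree(pos)
    bonded: dict[int, set[int]] = {i: set() for i in range(len(sites))}
    for i, j in tree.query_pairs(COVALENT_CUTOFF):
        bonded[i].add(j)
        bonded[j].add(i)
    onethree: dict[int, set[int]] = {}
    for i, nbrs in bonded.items():
        acc = set()
        for n in nbrs:
            acc |= bonded[n]
        acc.discard(i)
        onethree[i] = acc - nbrs
    return bonded, onethree


def _query_residue(model: StructureModel, chain_id: str, auth_number: int,
                   icode: str) -> Residue:
    from .chemistry import CANONICAL_AA3, RNA_RESNAMES
    res = model.chain(chain_id).residue(auth_number, icode)
    if res.name not in CANONICAL_AA3 and res.name not in RNA_RESNAMES:
        raise UnknownChemistryError(
            f"no donor/acceptor chemistry for residue {res.name!r}")
    return res


def _paired_sites(model: StructureModel, chain_id: str, auth_number: int,
                  icode: str, radius: float, config: ContactConfig):
    """Shared machinery: query sites, in-range pairs, bonded exclusions."""
    _query_residue(model, chain_id, auth_number, icode)
    all_sites = _sites(model, config.include_waters)
    index = {s: i for i, s in enumerate(all_sites)}
    query = [s for s in all_sites
             if s.residue_id == (chain_id, auth_number, icode)]
    pairs = neighbors_within(model, query, radius, config)
    bonded, onethree = _bonded_maps(all_sites)

    def excluded(q: AtomSite, e: AtomSite) -> bool:
        qi, ei = index[q], index[e]
        return ei in bonded[qi] or ei in onethree[qi]

    return query, pairs, excluded


def detect_hbonds(model: StructureModel, chain_id: str, auth_number: int,
                  icode: str = "", bands: HBondBands = DEFAULT_BANDS,
                  config: ContactConfig = DEFAULT_CONFIG) -> list[HBond]:
    """Hydrogen bonds of one residue: complementary donor/acceptor heavy-atom
    pairs with 2.2 <= d <= 4.0 A, excluding covalently bonded and 1-3 pairs.

    An atom pair yields a single bond; when both atoms could serve either
    role the direction is recorded as ambiguous.
    """
    query, pairs, excluded = _paired_sites(model, chain_id, auth_number,
                                           icode, bands.radius, config)
    out = []
    for q, e, d in sorted(pairs, key=lambda t: (t[2], t[0].atom_name, t[1].label())):
        if d < bands.too_close or d > bands.weak:
            continue
        rq = atom_polar_role(q.res_name, q.atom_name, config)
        re_ = atom_polar_role(e.res_name, e.atom_name, config)
        if rq == NONE or re_ == NONE:
            continue
        q_donates = rq in (DONOR, BOTH) and re_ in (ACCEPTOR, BOTH)
        q_accepts = rq in (ACCEPTOR, BOTH) and re_ in (DONOR, BOTH)
        if not (q_donates or q_accepts):
            continue
        if excluded(q, e):
            continue
        if config.donor_angle_filter and not _donor_angle_ok(model, q, e, config):
            continue
        direction = ("ambiguous" if (q_donates and q_accepts)
                     else "donor" if q_donates else "acceptor")
        out.append(HBond(atom=q, partner=e, distance=d,
                         band=classify_hbond_distance(d, bands),
                         direction=direction))
    return out


def _donor_angle_ok(model: StructureModel, q: AtomSite, e: AtomSite,
                    config: ContactConfig) -> bool:
    """Loose D-A-AA angle screen using the acceptor's bonded neighbor."""
    from .geometry import bond_angle
    sites = _sites(model, config.include_waters)
    pos = np.array([s.pos for s in sites])
    tree = cKDTree(pos)
    epos = np.array(e.pos)
    for j in tree.query_ball_point(e.pos, COVALENT_CUTOFF):
        s = sites[j]
        if s == e:
            continue
        ang = bond_angle(np.array(q.pos), epos, pos[j])
        if ang < config.min_donor_angle:
            return False
    return True


def detect_polar_contacts(model: StructureModel, chain_id: str,
                          auth_number: int, icode: str = "",
                          radius: float = 4.0,
                          config: ContactConfig = DEFAULT_CONFIG,
                          ) -> list[PolarContact]:
    """All polar-polar heavy-atom pairs of one residue within ``radius``,
    with the same bonded/1-3 exclusions as hydrogen-bond detection but no
    role complementarity or banding: the superset the hydrogen bonds live in."""
    query, pairs, excluded = _paired_sites(model, chain_id, auth_number,
                                           icode, radius, config)
    out = []
    for q, e, d in sorted(pairs, key=lambda t: (t[2], t[0].atom_name, t[1].label())):
        if atom_polar_role(q.res_name, q.atom_name, config) == NONE:
            continue
        if atom_polar_role(e.res_name, e.atom_name, config) == NONE:
            continue
        if excluded(q, e):
            continue
        out.append(PolarContact(atom=q, partner=e, distance=d))
    return out


def residue_contacts(model: StructureModel, chain_id: str, auth_number: int,
                     icode: str = "", bands: HBondBands = DEFAULT_BANDS,
                     config: ContactConfig = DEFAULT_CONFIG) -> ResidueContacts:
    """Hydrogen bonds, polar contacts and raw shell size for one residue."""
    res = model.chain(chain_id).residue(auth_number, icode)
    hb = detect_hbonds(model, chain_id, auth_number, icode, bands, config)
    pc = detect_polar_contacts(model, chain_id, auth_number, icode,
                               bands.radius, config)
    query = [s for s in _sites(model, config.include_waters)
             if s.residue_id == (chain_id, auth_number, icode)]
    shell = neighbors_within(model, query, bands.radius, config)
    return ResidueContacts(chain_id, auth_number, icode, res.name,
                           hbonds=hb, polar=pc, neighbor_count=len(shell))


def diff_contacts(wt: ResidueContacts, mut: ResidueContacts) -> ContactDiff:
    """Gained/lost interactions between wild-type and mutant contact sets.

    Both sides must describe the same residue address and have been computed
    with identical configuration. Interactions are keyed by partner residue
    identity + partner atom + own atom name, so backbone and shared side-chain
    atoms compare stably while atoms unique to one side count as gained/lost.
    """
    if (wt.chain_id, wt.res_number, wt.icode) != (mut.chain_id, mut.res_number, mut.icode):
        raise ValueError(
            f"diff of different residues: {wt.chain_id}/{wt.res_number}{wt.icode} "
            f"vs {mut.chain_id}/{mut.res_number}{mut.icode}")
    wt_hb = {h.key: h for h in wt.hbonds}
    mut_hb = {h.key: h for h in mut.hbonds}
    wt_pc = {p.key: p for p in wt.polar}
    mut_pc = {p.key: p for p in mut.polar}
    return ContactDiff(
        chain_id=wt.chain_id, res_number=wt.res_number, icode=wt.icode,
        gained_hbonds={k: mut_hb[k] for k in mut_hb.keys() - wt_hb.keys()},
        lost_hbonds={k: wt_hb[k] for k in wt_hb.keys() - mut_hb.keys()},
        gained_polar={k: mut_pc[k] for k in mut_pc.keys() - wt_pc.keys()},
        lost_polar={k: wt_pc[k] for k in wt_pc.keys() - mut_pc.keys()},
    )
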