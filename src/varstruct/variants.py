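"""Protein missense variants: HGVS parsing, Grantham scoring, protein-domain
localization, and the built-in PRPF31 variant catalogue.

The catalogue ships the thirteen PRPF31 missense variants assembled in the
source study of this pipeline (eleven previously published missense variants,
one published variant since shown to act through splicing, and the study's
own Ile114Asn), together with their verbatim external annotations (splicing
predictor text, SIFT, PolyPhen) and per-variant structural evidence flags.
External annotations are carried as text and never recomputed.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

from .chemistry import AA_1TO3, AA_3TO1
from .grantham import (DEFAULT_BANDS, GranthamBands, grantham_class,
                       grantham_distance)


class VariantParseError(ValueError):
    """Rejected variant string; ``reason`` is one of
    synonymous / nonsense / frameshift / unparsable."""

    def __init__(self, message: str, reason: str):
        super().__init__(message)
        self.reason = reason


@dataclass(frozen=True)
class ProteinVariant:
    ref_aa: str        # 3-letter
    position: int
    alt_aa: str        # 3-letter
    raw_hgvs: str = ""

    def __post_init__(self):
        if self.ref_aa not in AA_3TO1 or self.alt_aa not in AA_3TO1:
            raise VariantParseError(
                f"non-canonical amino acid in {self.raw_hgvs or self!r}", "unparsable")
        if self.ref_aa == self.alt_aa:
            raise VariantParseError(
                f"synonymous change {self.raw_hgvs!r}", "synonymous")
        if self.position < 1:
            raise VariantParseError(
                f"position must be >= 1 in {self.raw_hgvs!r}", "unparsable")

    def short(self) -> str:
        return f"{self.ref_aa}{self.position}{self.alt_aa}"

    @property
    def grantham_score(self) -> int:
        return grantham_distance(self.ref_aa, self.alt_aa)


_TER_TOKENS = {"TER", "*", "X"}
_HGVS_RE = re.compile(
    r"^(?:p\.)?\(?([A-Za-z*]{1,3})(\d+)([A-Za-z*=]{1,3})\)?$")


def _normalize_aa(token: str, raw: str) -> str:
    up = token.strip().upper()
    if up in _TER_TOKENS:
        return "TER"
    if len(up) == 1 and up in AA_1TO3:
        return AA_1TO3[up]
    if up in AA_3TO1:
        return up
    raise VariantParseError(f"unknown amino-acid code {token!r} in {raw!r}",
                            "unparsable")


def parse_protein_hgvs(text: str) -> ProteinVariant:
    """Parse a protein substitution in HGVS-style notation.

    Accepts ``p.Ile114Asn``, ``Ile114Asn`` and one-letter ``I114N`` forms.
    Only missense substitutions pass: synonymous, nonsense (Ter/*),
    frameshift and anything unparsable are rejected with a distinct reason.
    """
    raw = text.strip()
    if not raw:
        raise VariantParseError("empty variant string", "unparsable")
    if re.search(r"fs", raw, flags=re.IGNORECASE):
        raise VariantParseError(f"frameshift variant {raw!r}", "frameshift")
    if raw.endswith("="):
        raise VariantParseError(f"synonymous variant {raw!r}", "synonymous")
    m = _HGVS_RE.match(raw)
    if not m:
        raise VariantParseError(f"cannot parse variant {raw!r}", "unparsable")
    ref_t, pos, alt_t = m.groups()
    ref = _normalize_aa(ref_t, raw)
    alt = _normalize_aa(alt_t, raw)
    if alt == "TER":
        raise VariantParseError(f"nonsense variant {raw!r}", "nonsense")
    if ref == "TER":
        raise VariantParseError(f"stop-codon reference in {raw!r}", "unparsable")
    if ref == alt:
        raise VariantParseError(f"synonymous change {raw!r}", "synonymous")
    return ProteinVariant(ref_aa=ref, position=int(pos), alt_aa=alt, raw_hgvs=raw)


# ---------------------------------------------------------------------------
# Protein domains

@dataclass(frozen=True)
class DomainEntry:
    label: str
    start: int  # 1-based inclusive
    end: int


#: Domain localizations of the catalogued PRPF31 positions. Only the flexible
#: loop has published residue boundaries (256-265); every other entry records
#: the localization printed for a catalogued variant position, and residues
#: between entries are deliberately left unassigned rather than inventing
#: domain boundaries.
DEFAULT_DOMAINS: tuple[DomainEntry, ...] = (
    DomainEntry("Coiled coil domain alpha helix 1", 107, 107),
    DomainEntry("Coiled coil domain alpha helix 1", 114, 114),
    DomainEntry("Coiled coil tip alpha helix 3", 138, 138),
    DomainEntry("Coiled coil domain alpha helix 6", 194, 194),
    DomainEntry("Coiled coil domain alpha helix 6", 197, 197),
    DomainEntry("Coiled coil domain alpha helix 6", 216, 216),
    DomainEntry("Flexible loop", 256, 265),
    DomainEntry("Nop domain alpha helix 12", 288, 288),
    DomainEntry("Nop domain alpha helix 12", 291, 291),
    DomainEntry("Nop domain alpha helix 12", 299, 299),
    DomainEntry("C-terminal domain", 408, 408),
    DomainEntry("C-terminal domain", 458, 458),
)

UNASSIGNED = "unassigned"


def locate_domain(position: int,
                  domains: tuple[DomainEntry, ...] = DEFAULT_DOMAINS) -> str:
    """Label of the first domain range containing ``position`` (1-based,
    inclusive boundaries), or "unassigned"."""
    if position < 1:
        raise ValueError(f"position must be >= 1, got {position}")
    for entry in domains:
        if entry.start <= position <= entry.end:
            return entry.label
    return UNASSIGNED


# ---------------------------------------------------------------------------
# Variant records and the built-in catalogue

FLAG_VALUES = ("Y", "N", "unknown")


@dataclass
class VariantRecord:
    cdna_hgvs: str
    variant: ProteinVariant
    source: str                    # "published" | "this_study"
    domain: str = UNASSIGNED
    splicing_prediction: str = ""  # verbatim external annotation
    splicing_confirmed: bool = False
    sift: str = ""                 # verbatim
    polyphen: str = ""             # verbatim
    grantham_as_published: Optional[int] = None
    affects_hbond_within: str = "unknown"
    affects_hbond_other: str = "unknown"
    hbond_other_partner: str = ""
    affects_polar_contacts: str = "unknown"
    flag_reason: str = ""

    # computed, never taken from the annotation columns
    grantham_score: int = field(init=False)
    grantham_class: str = field(init=False)

    def __post_init__(self):
        self.grantham_score = self.variant.grantham_score
        self.grantham_class = grantham_class(self.grantham_score)
        for f in (self.affects_hbond_within, self.affects_hbond_other,
                  self.affects_polar_contacts):
            if f not in FLAG_VALUES:
                raise ValueError(f"flag must be one of {FLAG_VALUES}, got {f!r}")


_CATALOGUE_RESOURCE = "prpf31_catalogue.tsv"


def _flag(text: str) -> str:
    text = text.strip()
    return "unknown" if text in ("-", "", "–") else text


def _records_from_rows(rows) -> list[VariantRecord]:
    records = []
    for row in rows:
        variant = parse_protein_hgvs(row["protein_hgvs"])
        published = row.get("grantham_published", "").strip()
        rec = VariantRecord(
            cdna_hgvs=row["cdna_hgvs"].strip(),
            variant=variant,
            source=row["source"].strip(),
            domain=row["location"].strip(),
            splicing_prediction=row.get("splicing_prediction", "").strip(),
            splicing_confirmed=row.get("splicing_confirmed", "").strip() == "yes",
            sift=row.get("sift", "").strip(),
            polyphen=row.get("polyphen", "").strip(),
            grantham_as_published=int(published) if published else None,
            affects_hbond_within=_flag(row.get("affects_hbond_within", "-")),
            affects_hbond_other=_flag(row.get("affects_hbond_other", "-")),
            hbond_other_partner=row.get("hbond_other_partner", "").strip(),
            affects_polar_contacts=_flag(row.get("affects_polar_contacts", "-")),
        )
        if rec.affects_hbond_within == "unknown":
            rec.flag_reason = "not structurally analyzed (splicing variant)"
        records.append(rec)
    return records


def load_catalogue(path: str) -> list[VariantRecord]:
    """Load a user variant catalogue in the packaged TSV schema."""
    with open(path, newline="") as fh:
        return _records_from_rows(csv.DictReader(fh, delimiter="\t"))


def load_builtin_catalogue() -> list[VariantRecord]:
    """The packaged PRPF31 missense-variant catalogue (13 records)."""
    ref = resources.files("varstruct.data").joinpath(_CATALOGUE_RESOURCE)
    with ref.open(newline="") as fh:
        return _records_from_rows(csv.DictReader(fh, delimiter="\t"))


__all__ = [
    "ProteinVariant", "VariantParseError", "parse_protein_hgvs",
    "DomainEntry", "DEFAULT_DOMAINS", "locate_domain", "UNASSIGNED",
    "VariantRecord", "load_catalogue", "load_builtin_catalogue",
    "grantham_distance", "grantham_class", "GranthamBands", "DEFAULT_BANDS",
]
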