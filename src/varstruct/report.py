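"""Per-variant structural-evidence reports.

Integrates the variant catalogue (Grantham score and band, domain label,
verbatim external annotations) with the structural contact-diff evidence
into one row per variant. Flags are copied from computed diffs exactly and
are "unknown" wherever no structural analysis ran; no pathogenicity verdict
is ever synthesized — that judgment stays with the clinician.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .contacts import (ContactConfig, ContactDiff, HBondBands, DEFAULT_BANDS,
                       DEFAULT_CONFIG, diff_contacts, residue_contacts)
from .model import StructureModel
from .mutagenesis import (DEFAULT_MUTATION_CONFIG, MutagenesisError,
                          MutationConfig, UnmodelledResidueError,
                          mutate_residue)
from .variants import ProteinVariant, VariantRecord

TSV_COLUMNS = (
    "cdna_hgvs", "protein", "position", "domain", "grantham_score",
    "grantham_class", "splicing_prediction", "sift", "polyphen",
    "affects_hbond_within", "affects_hbond_other", "hbond_partners",
    "affects_polar_contacts", "status", "notes",
)


@dataclass
class EvidenceRow:
    cdna_hgvs: str
    protein: str
    position: int
    domain: str
    grantham_score: int
    grantham_class: str
    splicing_prediction: str = ""
    sift: str = ""
    polyphen: str = ""
    affects_hbond_within: str = "unknown"
    affects_hbond_other: str = "unknown"
    hbond_partners: str = ""
    affects_polar_contacts: str = "unknown"
    status: str = "ok"
    notes: str = ""

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in TSV_COLUMNS}


class ReportError(ValueError):
    pass


def _diff_key(variant: ProteinVariant) -> str:
    return variant.short()


def build_report(records: Sequence[VariantRecord],
                 diffs: Optional[dict] = None) -> list[EvidenceRow]:
    """One evidence row per catalogue record, ordered by protein position
    then variant residue.

    ``diffs`` maps a variant (ProteinVariant, or its "Xaa123Yaa" string) to a
    computed :class:`ContactDiff`; rows without a diff keep all structural
    flags "unknown". A diff for a variant absent from ``records`` is a
    misuse error.
    """
    diffs = dict(diffs or {})
    normalized: dict[str, ContactDiff] = {}
    for key, diff in diffs.items():
        k = _diff_key(key) if isinstance(key, ProteinVariant) else str(key)
        normalized[k] = diff
    known = {_diff_key(r.variant) for r in records}
    unknown = set(normalized) - known
    if unknown:
        raise ReportError(f"diffs supplied for variants not in the records: "
                          f"{sorted(unknown)}")
    rows = []
    for rec in sorted(records, key=lambda r: (r.variant.position, r.variant.alt_aa)):
        row = EvidenceRow(
            cdna_hgvs=rec.cdna_hgvs,
            protein=rec.variant.short(),
            position=rec.variant.position,
            domain=rec.domain,
            grantham_score=rec.grantham_score,
            grantham_class=rec.grantham_class,
            splicing_prediction=rec.splicing_prediction,
            sift=rec.sift,
            polyphen=rec.polyphen,
        )
        diff = normalized.get(_diff_key(rec.variant))
        if diff is not None:
            row.affects_hbond_within = diff.affects_hbond_within
            row.affects_hbond_other = diff.affects_hbond_other
            row.hbond_partners = ";".join(diff.interchain_partners)
            row.affects_polar_contacts = diff.affects_polar_contacts
        elif rec.flag_reason:
            row.notes = rec.flag_reason
        rows.append(row)
    return rows


def render_report(rows: Sequence[EvidenceRow], format: str = "tsv") -> str:
    """Serialize evidence rows as tsv, json, or a markdown grid."""
    if not rows:
        raise ReportError("no rows to render")
    if format == "tsv":
        out = io.StringIO()
        out.write("\t".join(TSV_COLUMNS) + "\n")
        for r in rows:
            out.write("\t".join(str(v) for v in r.as_dict().values()) + "\n")
        return out.getvalue()
    if format == "json":
        return json.dumps({"schema": "varstruct-evidence-row/1",
                           "rows": [r.as_dict() for r in rows]},
                          indent=2, sort_keys=True) + "\n"
    if format == "markdown":
        head = "| " + " | ".join(TSV_COLUMNS) + " |"
        sep = "|" + "|".join(" --- " for _ in TSV_COLUMNS) + "|"
        body = ["| " + " | ".join(str(v) for v in r.as_dict().values()) + " |"
                for r in rows]
        return "\n".join([head, sep, *body]) + "\n"
    raise ReportError(f"unknown report format {format!r}")


def parse_report_tsv(text: str) -> list[EvidenceRow]:
    """Inverse of ``render_report(..., "tsv")``."""
    lines = [ln for ln in text.splitlines() if ln]
    header = lines[0].split("\t")
    if tuple(header) != TSV_COLUMNS:
        raise ReportError("unexpected TSV header")
    rows = []
    for ln in lines[1:]:
        vals = dict(zip(TSV_COLUMNS, ln.split("\t")))
        vals["position"] = int(vals["position"])
        vals["grantham_score"] = int(vals["grantham_score"])
        rows.append(EvidenceRow(**vals))
    return rows


# ---------------------------------------------------------------------------
# End-to-end analysis

@dataclass
class AnalysisResult:
    rows: list[EvidenceRow]
    manifest: dict
    failures: dict = field(default_factory=dict)  # variant -> reason


def analyze_variants(model: StructureModel, chain_id: str,
                     records: Sequence[VariantRecord],
                     bands: HBondBands = DEFAULT_BANDS,
                     contact_config: ContactConfig = DEFAULT_CONFIG,
                     mutation_config: MutationConfig = DEFAULT_MUTATION_CONFIG,
                     entity_map: Optional[dict] = None,
                     skip_splicing_confirmed: bool = True,
                     ) -> AnalysisResult:
    """Run the full structural pipeline for each record on one chain.

    Per variant: select the residue, rebuild the variant side chain, compute
    wild-type and mutant contact sets, diff them, and flag the row. A variant
    that cannot be modeled (unresolved position, reference mismatch) is
    recorded with status "unmodelled"/"error" and the run continues — batch
    semantics, mirroring summary tables where some variants carry no
    structural columns.
    """
    if entity_map:
        model.apply_entity_map(entity_map)
    diffs: dict[str, ContactDiff] = {}
    statuses: dict[str, tuple[str, str]] = {}
    for rec in records:
        v = rec.variant
        key = v.short()
        if skip_splicing_confirmed and rec.splicing_confirmed:
            statuses[key] = ("skipped", "not structurally analyzed (splicing variant)")
            continue
        try:
            mut = mutate_residue(model, chain_id, v.position,
                                 v.alt_aa, expected_ref=v.ref_aa,
                                 config=mutation_config)
            wt_c = residue_contacts(model, chain_id, v.position,
                                    bands=bands, config=contact_config)
            mu_c = residue_contacts(mut.model, chain_id, v.position,
                                    bands=bands, config=contact_config)
            diffs[key] = diff_contacts(wt_c, mu_c)
            statuses[key] = ("ok", "; ".join(mut.notes))
        except UnmodelledResidueError as exc:
            statuses[key] = ("unmodelled", str(exc))
        except MutagenesisError as exc:
            statuses[key] = ("error", str(exc))
    rows = build_report(records, diffs)
    for row in rows:
        status, note = statuses.get(row.protein, ("ok", ""))
        row.status = status
        if note:
            row.notes = note
    manifest = {
        "structure": model.id,
        "chain": chain_id,
        "contact_radius_A": bands.radius,
        "hbond_bands_A": {"too_close": bands.too_close, "strong": bands.strong,
                          "moderate": bands.moderate, "weak": bands.weak},
        "clash_cutoff_A": mutation_config.clash_cutoff,
        "include_waters": contact_config.include_waters,
        "include_sulfur": contact_config.include_sulfur,
        "donor_angle_filter": contact_config.donor_angle_filter,
        "entity_map": dict(entity_map or {}),
        "variants": sorted(r.variant.short() for r in records),
    }
    failures = {k: note for k, (status, note) in statuses.items()
                if status not in ("ok",)}
    return AnalysisResult(rows=rows, manifest=manifest, failures=failures)
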