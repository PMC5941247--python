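"""VCF annotation with the computed metrics (VCF 4.3 semantics).

Sites are matched to variation records **by rsID and alternate allele
only** — the ID column must carry an rsID; chromosome/position are never
consulted, so no allele normalisation or liftover is attempted.  Twelve
metric fields (everything except ``vcf_match`` and the rsID itself, which
is already the VCF ID column) are appended to INFO, one value per
alternate allele in alt order, ``.`` for unmatched alleles.  Haplotype
records match when the site allele is a member of the haplotype's allele
list and are labelled as haplotypes.

The writer is deliberately line-based: input body lines are preserved
byte-for-byte except for the INFO extension, so stripping the added keys
restores the input exactly.  Values are sanitised for the VCF 4.3 reserved
characters (whitespace, semicolon, comma, equals) before insertion.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .calibration import CtpsRangeSet
from .classify import annotate_record
from .model import MISSING, VariantMetrics, VariationRecord, format_number, format_significance
from .scoring import EvaluationContext

logger = logging.getLogger(__name__)

#: metric field -> (VCF Type, Description); Number is always "A" (per alt).
_INFO_FIELDS: dict[str, tuple[str, str]] = {
    "VID": ("String", "ClinVar-style Variation ID"),
    "CVCS": ("String", "Database overall clinical significance"),
    "CVSZ": ("Integer", "Review-status star rating (0-4)"),
    "CVNA": ("Integer", "Number of valid criteria-based clinical assertions"),
    "CVDS": ("String", "Associated conditions/diseases"),
    "CVAL": ("String", "Record alternate allele"),
    "CVLE": ("String", "Date the overall significance was last evaluated"),
    "CVVT": ("String", "Variation type (Simple or Haplotype)"),
    "CTRS": ("Float", "Aggregate weighted raw score of clinical assertions"),
    "CTAA": ("Float", "Mean whole-year age of valid clinical assertions"),
    "CTPS": ("String", "Predicted significance from calibrated score ranges"),
    "CTRR": ("Integer", "Reclassification priority rank 0-3"),
}

_SANITIZE = re.compile(r"[;,=\s]")


def sanitize(value: str) -> str:
    """Replace VCF-reserved characters with underscores."""
    return _SANITIZE.sub("_", value)


@dataclass(frozen=True)
class VcfAnnotationPlan:
    """The 12 INFO definitions added to annotated output."""

    key_prefix: str = "CT_"
    fields: Sequence[str] = tuple(_INFO_FIELDS)

    def __post_init__(self) -> None:
        if len(self.fields) != 12:
            raise ValueError("exactly 12 INFO fields are defined")

    def keys(self) -> list[str]:
        return [self.key_prefix + f for f in self.fields]

    def header_lines(self) -> list[str]:
        lines = []
        for f in self.fields:
            vtype, desc = _INFO_FIELDS[f]
            lines.append(
                f'##INFO=<ID={self.key_prefix}{f},Number=A,Type={vtype},'
                f'Description="{desc}">'
            )
        return lines


DEFAULT_PLAN = VcfAnnotationPlan()


def _metric_values(m: VariantMetrics) -> dict[str, str]:
    return {
        "VID": sanitize(m.vid) or MISSING,
        "CVCS": sanitize(format_significance(m.cvcs)),
        "CVSZ": str(m.cvsz),
        "CVNA": str(m.cvna),
        "CVDS": sanitize("|".join(m.cvds)) if m.cvds else MISSING,
        "CVAL": sanitize(m.cval) or MISSING,
        "CVLE": m.cvle.isoformat() if m.cvle else MISSING,
        "CVVT": sanitize(m.cvvt) or MISSING,
        "CTRS": format_number(m.ctrs),
        "CTAA": format_number(m.ctaa) if m.ctaa is not None else MISSING,
        "CTPS": m.ctps.value if m.ctps is not None else MISSING,
        "CTRR": str(m.ctrr) if m.ctrr is not None else MISSING,
    }


def match_annotation(
    site: tuple[str, str, Sequence[str]],
    records: Sequence[VariationRecord],
    ranges: CtpsRangeSet,
    ctx: EvaluationContext,
) -> Optional[list[Optional[VariantMetrics]]]:
    """Per-alternate-allele metrics for a VCF site, or None if nothing matches.

    ``site`` is (id, ref, alts).  For each alt the record whose rsID list
    contains the site rsID and whose allele matches is annotated: simple
    records match on the record's alternate allele, haplotype records by
    membership of the site allele in the haplotype allele list.
    """
    site_id, _ref, alts = site
    rsids = {
        tok[2:] if tok.lower().startswith("rs") else tok
        for tok in site_id.split(";")
        if tok and tok != MISSING
    }
    if not rsids:
        return None
    per_alt: list[Optional[VariantMetrics]] = []
    matched = False
    for alt in alts:
        hit = None
        for rec in records:
            if not rsids.intersection(rec.rsids):
                continue
            if rec.variant_type == "Haplotype":
                if alt in rec.alt_alleles:
                    hit = rec
                    break
            elif alt in rec.alt_alleles:
                hit = rec
                break
        if hit is None:
            per_alt.append(None)
        else:
            matched = True
            per_alt.append(annotate_record(hit, ranges, ctx))
    return per_alt if matched else None


def annotate_vcf(
    in_path,
    out_path,
    records: Sequence[VariationRecord],
    ranges: CtpsRangeSet,
    ctx: EvaluationContext,
    plan: VcfAnnotationPlan = DEFAULT_PLAN,
) -> int:
    """Annotate a VCF file; returns the number of sites annotated.

    The header is preserved verbatim with 12 new INFO definitions inserted
    before #CHROM; body lines are preserved except that matched sites get
    the new keys appended to INFO (comma-separated per-alt values in alt
    order, '.' for unmatched alleles).  A pre-existing definition of any
    added key is an error.
    """
    with open(in_path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    out_lines: list[str] = []
    n_annotated = 0
    header_done = False
    existing = set()
    for lineno, line in enumerate(lines, 1):
        if line.startswith("##"):
            m = re.match(r"##INFO=<ID=([^,>]+)", line)
            if m:
                existing.add(m.group(1))
            out_lines.append(line)
            continue
        if line.startswith("#CHROM"):
            collisions = existing.intersection(plan.keys())
            if collisions:
                raise ValueError(f"INFO keys already defined in header: {sorted(collisions)}")
            out_lines.extend(plan.header_lines())
            out_lines.append(line)
            header_done = True
            continue
        if not line.strip():
            out_lines.append(line)
            continue
        if not header_done:
            raise ValueError(f"{in_path}:{lineno}: data line before #CHROM header")
        cols = line.split("\t")
        if len(cols) < 8:
            raise ValueError(f"{in_path}:{lineno}: expected >=8 VCF columns, got {len(cols)}")
        site_id, ref, alt_field = cols[2], cols[3], cols[4]
        alts = alt_field.split(",") if alt_field != MISSING else []
        per_alt = match_annotation((site_id, ref, alts), records, ranges, ctx)
        if per_alt is None:
            out_lines.append(line)
            continue
        n_annotated += 1
        pieces = []
        for f in plan.fields:
            vals = [
                _metric_values(m)[f] if m is not None else MISSING for m in per_alt
            ]
            pieces.append(f"{plan.key_prefix}{f}=" + ",".join(vals))
        addition = ";".join(pieces)
        cols[7] = addition if cols[7] == MISSING else cols[7] + ";" + addition
        out_lines.append("\t".join(cols))
    with open(out_path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(out_lines) + ("\n" if lines else ""))
    return n_annotated


def strip_annotations(
    in_path, out_path, plan: VcfAnnotationPlan = DEFAULT_PLAN
) -> None:
    """Remove the plan's INFO keys and header lines (round-trip inverse)."""
    keys = set(plan.keys())
    header_lines = set(plan.header_lines())
    out: list[str] = []
    with open(in_path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    for line in lines:
        if line.startswith("#"):
            if line in header_lines:
                continue
            out.append(line)
            continue
        if not line.strip():
            out.append(line)
            continue
        cols = line.split("\t")
        if len(cols) >= 8:
            entries = [
                e for e in cols[7].split(";") if e.split("=", 1)[0] not in keys
            ]
            cols[7] = ";".join(entries) if entries else MISSING
        out.append("\t".join(cols))
    with open(out_path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(out) + ("\n" if lines else ""))
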