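"""Reading variation records and identifier lists.

Two record sources share one in-memory model:

* the canonical *fixture format* — JSON lines, one record object per line,
  field names matching :class:`~clinrank.model.VariationRecord`, dates
  ISO-8601.  This is the stable, versionable test and batch input.
* a best-effort parser for a ClinVar variation-report XML subset
  (identifiers, review status, per-assertion significance/date/submitter
  category, alleles, trait names).  The live dialect evolves; the fixture
  format is authoritative.

ID lists are plain text, one ClinVar Variation ID or dbSNP rsID per line.
An rsID is not 1:1 with variation records — multi-allelic rsIDs map to one
record per allele — so rsID expansion returns every matching record.

A batched-fetch adapter contract is defined for callers that wire in a
network transport (e.g. NCBI E-utilities); no network code lives here and
the transport is always injected.
"""

from __future__ import annotations

import datetime
import json
import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence
from xml.etree import ElementTree

from .model import (
    AssertionSignificance,
    ClinicalAssertion,
    OverallSignificance,
    SubmitterCategory,
    VariationRecord,
    parse_assertion_significance,
    parse_overall_significance,
)

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# ID lists

@dataclass
class IdList:
    kind: str  # "vid" | "rsid"
    ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.kind not in ("vid", "rsid"):
            raise ValueError(f"unknown id kind {self.kind!r}")


def read_id_list(path, kind: str) -> IdList:
    """Read one identifier per line; blank lines are skipped with a warning.

    Duplicates are preserved in order.  A leading "rs" on rsIDs is stripped
    so both spellings match the record model.
    """
    ids: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            token = line.strip()
            if not token:
                logger.warning("%s:%d: blank line skipped", path, lineno)
                continue
            if kind == "rsid" and token.lower().startswith("rs"):
                token = token[2:]
            ids.append(token)
    if not ids:
        logger.warning("%s: empty identifier list", path)
    return IdList(kind=kind, ids=ids)


# --------------------------------------------------------------------------
# Fixture format (JSON lines)

def _parse_date(text: Optional[str]) -> Optional[datetime.date]:
    if not text or text in (".", "-"):
        return None
    return datetime.date.fromisoformat(text)


def _assertion_from_dict(obj: dict) -> ClinicalAssertion:
    sig_text = obj.get("significance")
    sig = parse_assertion_significance(sig_text) if sig_text else None
    if sig_text and sig is None:
        logger.warning("assertion significance %r outside the five-tier scale", sig_text)
    return ClinicalAssertion(
        significance=sig,
        last_evaluated=_parse_date(obj.get("last_evaluated")),
        submitter_category=SubmitterCategory(obj.get("submitter_category", "no_criteria")),
        submitter_name=obj.get("submitter_name", ""),
        conditions=list(obj.get("conditions", [])),
    )


def _record_from_dict(obj: dict) -> VariationRecord:
    cvcs_text = obj.get("cvcs")
    return VariationRecord(
        vid=str(obj["vid"]),
        rsids=[str(r) for r in obj.get("rsids", [])],
        cvcs=parse_overall_significance(cvcs_text) if cvcs_text else None,
        stars=int(obj.get("stars", 0)),
        variant_type=obj.get("variant_type", "Simple"),
        alt_alleles=list(obj.get("alt_alleles", [])),
        conditions=list(obj.get("conditions", [])),
        cv_last_evaluated=_parse_date(obj.get("cv_last_evaluated")),
        assertions=[_assertion_from_dict(a) for a in obj.get("assertions", [])],
    )


def record_to_dict(rec: VariationRecord) -> dict:
    """Fixture-format dictionary for one record (inverse of parsing)."""
    cvcs = rec.cvcs.value if isinstance(rec.cvcs, OverallSignificance) else rec.cvcs
    return {
        "vid": rec.vid,
        "rsids": list(rec.rsids),
        "cvcs": cvcs,
        "stars": rec.stars,
        "variant_type": rec.variant_type,
        "alt_alleles": list(rec.alt_alleles),
        "conditions": list(rec.conditions),
        "cv_last_evaluated": rec.cv_last_evaluated.isoformat()
        if rec.cv_last_evaluated
        else None,
        "assertions": [
            {
                "significance": a.significance.value if a.significance else None,
                "last_evaluated": a.last_evaluated.isoformat()
                if a.last_evaluated
                else None,
                "submitter_category": a.submitter_category.value,
                "submitter_name": a.submitter_name,
                "conditions": list(a.conditions),
            }
            for a in rec.assertions
        ],
    }


def read_fixture_records(path) -> list[VariationRecord]:
    """Parse a JSON-lines record file; malformed entries name their index."""
    records: list[VariationRecord] = []
    with open(path, encoding="utf-8") as fh:
        for index, line in enumerate(fh):
            if not line.strip():
                continue
            try:
                records.append(_record_from_dict(json.loads(line)))
            except (json.JSONDecodeError, KeyError, ValueError) as e:
                raise ValueError(f"{path}: malformed record at entry {index}: {e}") from e
    return records


def write_fixture_records(records: Iterable[VariationRecord], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(json.dumps(record_to_dict(rec)) + "\n")


def expand_rsid(rsid: str, records: Sequence[VariationRecord]) -> list[VariationRecord]:
    """All records whose rsID list contains the query, in input order.

    The rsID-to-record mapping is not 1:1: a multi-allelic rsID yields one
    record per allele.  No match returns an empty list with a warning.
    """
    query = rsid[2:] if rsid.lower().startswith("rs") else rsid
    hits = [rec for rec in records if query in rec.rsids]
    if not hits:
        logger.warning("rsID rs%s matches no record", query)
    return hits


# --------------------------------------------------------------------------
# ClinVar variation-report XML subset

#: Review-status text -> star rating (versioned lookup).
REVIEW_STATUS_STARS = {
    "practice guideline": 4,
    "reviewed by expert panel": 3,
    "criteria provided, multiple submitters, no conflicts": 2,
    "criteria provided, conflicting interpretations": 1,
    "criteria provided, single submitter": 1,
    "no assertion criteria provided": 0,
    "no assertion provided": 0,
}

_REVIEW_STATUS_CATEGORY = {
    "practice guideline": SubmitterCategory.PRACTICE_GUIDELINE,
    "reviewed by expert panel": SubmitterCategory.EXPERT_PANEL,
    "criteria provided, single submitter": SubmitterCategory.CRITERIA_PROVIDED,
    "criteria provided, multiple submitters, no conflicts": SubmitterCategory.CRITERIA_PROVIDED,
    "no assertion criteria provided": SubmitterCategory.NO_CRITERIA,
    "literature only": SubmitterCategory.LITERATURE_ONLY,
    "no assertion provided": SubmitterCategory.LITERATURE_ONLY,
}


def _submitter_category(status_text: str) -> SubmitterCategory:
    key = status_text.strip().lower()
    cat = _REVIEW_STATUS_CATEGORY.get(key)
    if cat is None:
        logger.warning("ambiguous submitter review status %r; treated as no_criteria", status_text)
        return SubmitterCategory.NO_CRITERIA
    return cat


def parse_clinvar_xml(document) -> list[VariationRecord]:
    """Parse a variation-report XML subset into records.

    ``document`` is a path, file object, or XML string.  Expected shape:
    ``VariationReport`` elements with ``VariationID``/``VariationType``
    attributes; an overall ``ClinicalSignificance`` child (review status,
    description, date last evaluated); ``Allele`` children carrying dbSNP
    cross-references and alternate alleles; and a ``ClinicalAssertionList``
    of per-submitter assertions.  Missing or blank fields are logged and
    the affected assertions marked invalid rather than aborting the parse.
    """
    if isinstance(document, str) and document.lstrip().startswith("<"):
        try:
            root = ElementTree.fromstring(document)
        except ElementTree.ParseError as e:
            raise ValueError(f"malformed XML: {e}") from e
    else:
        try:
            root = ElementTree.parse(document).getroot()
        except ElementTree.ParseError as e:
            raise ValueError(f"malformed XML: {e}") from e
    reports = root.iter("VariationReport") if root.tag != "VariationReport" else [root]
    records: list[VariationRecord] = []
    for report in reports:
        records.append(_parse_report(report))
    if not records:
        raise ValueError(
            "no VariationReport elements found; if this is not variation-report "
            "XML, convert it to the JSON-lines fixture format"
        )
    return records


def _text(parent, tag: str) -> Optional[str]:
    el = parent.find(tag)
    if el is None or el.text is None or not el.text.strip():
        return None
    return el.text.strip()


def _parse_report(report) -> VariationRecord:
    vid = report.get("VariationID", "")
    alleles = report.findall(".//Allele")
    rsids: list[str] = []
    alt_alleles: list[str] = []
    for allele in alleles:
        for xref in allele.findall(".//XRef"):
            if xref.get("DB") == "dbSNP":
                rsids.append(xref.get("ID", ""))
        alt = _text(allele, "AltAllele")
        if alt:
            alt_alleles.append(alt)
    variant_type = report.get(
        "VariationType", "Haplotype" if len(alleles) > 1 else "Simple"
    )
    overall = report.find("ClinicalSignificance")
    cvcs = None
    stars = 0
    cv_last = None
    if overall is not None:
        desc = _text(overall, "Description")
        if desc:
            cvcs = parse_overall_significance(desc)
        status = _text(overall, "ReviewStatus")
        if status:
            stars = REVIEW_STATUS_STARS.get(status.lower(), 0)
        cv_last = _parse_date(_text(overall, "DateLastEvaluated"))
    else:
        logger.warning("record %s: missing overall ClinicalSignificance", vid)
    conditions = sorted(
        {t.text.strip() for t in report.findall(".//TraitSet/Trait/Name") if t.text}
    )
    assertions: list[ClinicalAssertion] = []
    for el in report.findall(".//ClinicalAssertionList/ClinicalAssertion"):
        status = _text(el, "ReviewStatus") or ""
        sig_el = el.find("ClinicalSignificance")
        sig_text = _text(sig_el, "Description") if sig_el is not None else None
        date = _parse_date(_text(sig_el, "DateLastEvaluated")) if sig_el is not None else None
        if date is None:
            logger.warning(
                "record %s: assertion from %r lacks a date last evaluated",
                vid,
                el.get("SubmitterName", ""),
            )
        sig = parse_assertion_significance(sig_text) if sig_text else None
        assertions.append(
            ClinicalAssertion(
                significance=sig,
                last_evaluated=date,
                submitter_category=_submitter_category(status),
                submitter_name=el.get("SubmitterName", ""),
                conditions=[
                    t.text.strip() for t in el.findall(".//Trait/Name") if t.text
                ],
            )
        )
    return VariationRecord(
        vid=vid,
        rsids=rsids,
        cvcs=cvcs,
        stars=stars,
        variant_type=variant_type,
        alt_alleles=alt_alleles,
        conditions=conditions,
        cv_last_evaluated=cv_last,
        assertions=assertions,
    )


# --------------------------------------------------------------------------
# Batched-fetch adapter contract (transport injected; no network here)

@dataclass(frozen=True)
class FetchPolicy:
    """Batch sizes and retry budget for a remote record fetch."""

    elink_batch: int = 1000
    efetch_batch: int = 4500
    retries: int = 3

    def __post_init__(self) -> None:
        if not 1 <= self.elink_batch <= 1000:
            raise ValueError("elink_batch must be in [1, 1000]")
        if not 1 <= self.efetch_batch <= 10000:
            raise ValueError("efetch_batch must be in [1, 10000]")


class FetchError(RuntimeError):
    pass


def fetch_adapter(
    ids: IdList,
    policy: FetchPolicy,
    transport: Callable[[list[str]], object],
) -> list[object]:
    """Fetch raw documents for an ID list through an injected transport.

    The list is split into batches of at most ``policy.efetch_batch`` ids
    (``elink_batch`` for rsID lists, which require a link step first); each
    batch is retried up to ``policy.retries`` times on transport failure
    and results are concatenated in batch order.
    """
    size = policy.elink_batch if ids.kind == "rsid" else policy.efetch_batch
    out: list[object] = []
    for start in range(0, len(ids.ids), size):
        batch = ids.ids[start : start + size]
        last_error: Optional[Exception] = None
        for attempt in range(policy.retries):
            try:
                result = transport(batch)
                # per-batch result lists are concatenated, scalars appended
                if isinstance(result, list):
                    out.extend(result)
                else:
                    out.append(result)
                last_error = None
                break
            except Exception as e:  # transport failures are retried
                last_error = e
                logger.warning(
                    "batch starting at %d failed (attempt %d/%d): %s",
                    start,
                    attempt + 1,
                    policy.retries,
                    e,
                )
        if last_error is not None:
            raise FetchError(
                f"batch starting at index {start} failed after "
                f"{policy.retries} attempts"
            ) from last_error
    return out
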