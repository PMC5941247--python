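"""Predicted significance (CTPS) and reclassification rank (CTRR).

The predicted significance is the label of the calibrated score range that
contains a record's raw score, reported only when the record carries at
least two valid assertions.  The reclassification rank measures how far the
database's own aggregate significance sits from the prediction on the
seven-position scale (B, BLB, LB, US/CI, LP, PLP, P): one point per step,
one extra point per zone boundary crossed (benign <-> uncertain <->
pathogenic), capped at three.

The predicted significance rates evidence strength; it is not a clinical
classification and must not be used to assign significance to a variant —
that requires primary-evidence review under the ACMG/AMP guidelines.
"""

from __future__ import annotations

import logging
from typing import Optional, Union

from .calibration import CtpsRangeSet
from .model import (
    OverallSignificance,
    VariantMetrics,
    VariationRecord,
)
from .scoring import (
    EvaluationContext,
    compute_ctaa,
    compute_ctrs,
    count_valid,
)

logger = logging.getLogger(__name__)

#: Minimum number of valid assertions for a prediction to be reported.
MIN_VALID_ASSERTIONS = 2

CTRR_CAP = 3

_ZONES = {
    OverallSignificance.B: "benign",
    OverallSignificance.BLB: "benign",
    OverallSignificance.LB: "benign",
    OverallSignificance.US: "uncertain",
    OverallSignificance.CI: "uncertain",
    OverallSignificance.LP: "pathogenic",
    OverallSignificance.PLP: "pathogenic",
    OverallSignificance.P: "pathogenic",
}


def significance_zone(sig: OverallSignificance) -> str:
    """'benign', 'uncertain' or 'pathogenic' family of a scale position."""
    return _ZONES[sig]


def assign_ctps(
    ctrs: float, n_valid: int, ranges: CtpsRangeSet
) -> Optional[OverallSignificance]:
    """Predicted significance for a score, or None with <2 valid assertions."""
    if n_valid < MIN_VALID_ASSERTIONS:
        return None
    return ranges.classify(ctrs)


def compute_ctrr(
    cvcs: Union[OverallSignificance, str, None],
    ctps: Optional[OverallSignificance],
) -> Optional[int]:
    """Reclassification rank 0-3, or None when either side is unavailable.

    Rank = ordinal distance between the two significances plus one point
    per zone boundary crossed, capped at 3.  The conflicted status (CI)
    occupies the uncertain position.  Overall significances outside the
    mapped scale (e.g. "risk factor") yield None so batch runs never abort.
    """
    if ctps is None:
        return None
    if not isinstance(cvcs, OverallSignificance):
        if cvcs is not None:
            logger.warning(
                "overall significance %r is not on the 7-position scale; "
                "no reclassification rank computed",
                cvcs,
            )
        return None
    a, b = cvcs.ordinal, ctps.ordinal
    lo, hi = min(a, b), max(a, b)
    crossings = sum(1 for boundary in (3, 4) if lo <= boundary < hi)
    return min(CTRR_CAP, abs(a - b) + crossings)


def _vcf_match(rec: VariationRecord) -> str:
    """rsID / haplotype-allele association string for the vcf_match field."""
    if rec.variant_type == "Haplotype" or len(rec.rsids) > 1:
        parts = []
        for i, rsid in enumerate(rec.rsids):
            allele = rec.alt_alleles[i] if i < len(rec.alt_alleles) else ""
            parts.append(f"rs{rsid}:{allele}" if allele else f"rs{rsid}")
        tag = "Haplotype" if rec.variant_type == "Haplotype" else "Multi"
        return f"{tag}[" + "|".join(parts) + "]" if parts else tag
    return ""


def annotate_record(
    rec: VariationRecord, ranges: CtpsRangeSet, ctx: EvaluationContext
) -> VariantMetrics:
    """Compute the full 14-field metric row for one variation record.

    Database fields are copied through; CVNA/CTRS/CTAA are computed from
    the assertion list; CTPS/CTRR require >=2 valid assertions and a
    Mendelian overall significance respectively, else they are missing.
    """
    n_valid = count_valid(rec.assertions)
    ctrs = compute_ctrs(rec.assertions, ctx)
    ctaa = compute_ctaa(rec.assertions, ctx)
    ctps = assign_ctps(ctrs, n_valid, ranges)
    ctrr = compute_ctrr(rec.cvcs, ctps)
    if not rec.rsids:
        logger.warning("record %s carries no rsID", rec.vid)
    return VariantMetrics(
        vid=str(rec.vid),
        rsid=",".join(f"rs{r}" for r in rec.rsids),
        cvcs=rec.cvcs,
        cvsz=rec.stars,
        cvna=n_valid,
        cvds=list(rec.conditions),
        cval=",".join(rec.alt_alleles),
        cvle=rec.cv_last_evaluated,
        cvvt=rec.variant_type,
        ctrs=ctrs,
        ctaa=ctaa,
        ctps=ctps,
        ctrr=ctrr,
        vcf_match=_vcf_match(rec),
    )
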