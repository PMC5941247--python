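"""Domain model for clinical-assertion aggregation.

The unit of evidence is a :class:`ClinicalAssertion` — one submitter's
interpretation of a variant's clinical significance, carrying the five-tier
ACMG/AMP label (Benign, Likely benign, Uncertain significance, Likely
pathogenic, Pathogenic), the date the significance was last evaluated, and
the submitter's review-status category.  A :class:`VariationRecord` is one
ClinVar-style variation report: identifiers, the database's own aggregate
significance and star rating, alleles, and the list of assertions.

Only *valid* assertions enter any score: the submitter must have published
assertion criteria (practice guideline, expert panel, or criteria-provided
tiers), the significance must be one of the five Mendelian labels, and a
last-evaluated date must be present.  Literature-only records (e.g. OMIM
citations) are evidence, not clinical assertions, and are excluded, as are
assertions with incomplete data.
"""

from __future__ import annotations

import datetime
import enum
from dataclasses import dataclass, field
from typing import Optional, Union


class AssertionSignificance(enum.Enum):
    """Five-tier Mendelian significance of a single assertion, ordered B < P."""

    B = "B"
    LB = "LB"
    US = "US"
    LP = "LP"
    P = "P"

    @property
    def rank(self) -> int:
        return _ASSERTION_RANK[self]

    def __lt__(self, other: "AssertionSignificance") -> bool:
        if not isinstance(other, AssertionSignificance):
            return NotImplemented
        return self.rank < other.rank


_ASSERTION_RANK = {
    AssertionSignificance.B: 0,
    AssertionSignificance.LB: 1,
    AssertionSignificance.US: 2,
    AssertionSignificance.LP: 3,
    AssertionSignificance.P: 4,
}


class OverallSignificance(enum.Enum):
    """Seven-position aggregate significance scale of a variation report.

    ``CI`` (conflicting interpretations) shares the ordinal position of
    ``US``: a conflicted record is treated as uncertain when measuring
    reclassification distance.
    """

    B = "B"
    BLB = "BLB"
    LB = "LB"
    US = "US"
    CI = "CI"
    LP = "LP"
    PLP = "PLP"
    P = "P"

    @property
    def ordinal(self) -> int:
        """Position 1-7 on the reclassification scale (CI == US == 4)."""
        return _OVERALL_ORDINAL[self]


_OVERALL_ORDINAL = {
    OverallSignificance.B: 1,
    OverallSignificance.BLB: 2,
    OverallSignificance.LB: 3,
    OverallSignificance.US: 4,
    OverallSignificance.CI: 4,
    OverallSignificance.LP: 5,
    OverallSignificance.PLP: 6,
    OverallSignificance.P: 7,
}

#: Labels accepted when parsing overall significance text, beyond enum values.
OVERALL_ALIASES = {
    "benign": OverallSignificance.B,
    "benign/likely benign": OverallSignificance.BLB,
    "likely benign": OverallSignificance.LB,
    "uncertain significance": OverallSignificance.US,
    "conflicting interpretations of pathogenicity": OverallSignificance.CI,
    "likely pathogenic": OverallSignificance.LP,
    "pathogenic/likely pathogenic": OverallSignificance.PLP,
    "pathogenic": OverallSignificance.P,
    "b": OverallSignificance.B,
    "blb": OverallSignificance.BLB,
    "b/lb": OverallSignificance.BLB,
    "lb": OverallSignificance.LB,
    "us": OverallSignificance.US,
    "ci": OverallSignificance.CI,
    "lp": OverallSignificance.LP,
    "plp": OverallSignificance.PLP,
    "p/lp": OverallSignificance.PLP,
    "p": OverallSignificance.P,
}

#: Assertion significance text accepted on input.
ASSERTION_ALIASES = {
    "benign": AssertionSignificance.B,
    "likely benign": AssertionSignificance.LB,
    "uncertain significance": AssertionSignificance.US,
    "likely pathogenic": AssertionSignificance.LP,
    "pathogenic": AssertionSignificance.P,
    "b": AssertionSignificance.B,
    "lb": AssertionSignificance.LB,
    "us": AssertionSignificance.US,
    "lp": AssertionSignificance.LP,
    "p": AssertionSignificance.P,
}


def parse_overall_significance(text: str) -> Union[OverallSignificance, str]:
    """Map free text to the seven-position scale; unmapped text passes through.

    Non-Mendelian significances ("drug response", "risk factor", ...) are
    carried verbatim: such records still receive a raw score and assertion
    age, but no predicted significance or reclassification rank.
    """
    return OVERALL_ALIASES.get(text.strip().lower(), text)


def parse_assertion_significance(text: str) -> Optional[AssertionSignificance]:
    """Map free text to a five-tier label, or None if outside the scale."""
    return ASSERTION_ALIASES.get(text.strip().lower())


class SubmitterCategory(enum.Enum):
    PRACTICE_GUIDELINE = "practice_guideline"
    EXPERT_PANEL = "expert_panel"
    CRITERIA_PROVIDED = "criteria_provided"
    NO_CRITERIA = "no_criteria"
    LITERATURE_ONLY = "literature_only"


#: Categories whose submissions carry published assertion criteria.
CRITERIA_CATEGORIES = frozenset(
    {
        SubmitterCategory.PRACTICE_GUIDELINE,
        SubmitterCategory.EXPERT_PANEL,
        SubmitterCategory.CRITERIA_PROVIDED,
    }
)


@dataclass
class ClinicalAssertion:
    """One submitter's significance call.

    ``significance`` or ``last_evaluated`` may be absent (None); such
    assertions are retained on the record but never scored.
    """

    significance: Optional[AssertionSignificance] = None
    last_evaluated: Optional[datetime.date] = None
    submitter_category: SubmitterCategory = SubmitterCategory.CRITERIA_PROVIDED
    submitter_name: str = ""
    conditions: list[str] = field(default_factory=list)


def is_valid_assertion(a: ClinicalAssertion) -> bool:
    """True iff the assertion can contribute to scoring.

    Requires a criteria-bearing submitter category, a significance on the
    five-tier Mendelian scale, and a last-evaluated date.
    """
    return (
        a.submitter_category in CRITERIA_CATEGORIES
        and a.significance is not None
        and a.last_evaluated is not None
    )


@dataclass
class VariationRecord:
    """A ClinVar-style variation report."""

    vid: str
    rsids: list[str] = field(default_factory=list)
    cvcs: Union[OverallSignificance, str, None] = None
    stars: int = 0
    variant_type: str = "Simple"
    alt_alleles: list[str] = field(default_factory=list)
    conditions: list[str] = field(default_factory=list)
    cv_last_evaluated: Optional[datetime.date] = None
    assertions: list[ClinicalAssertion] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0 <= int(self.stars) <= 4:
            raise ValueError(f"stars must be 0-4, got {self.stars}")


MISSING = "."


@dataclass
class VariantMetrics:
    """The 14 output fields for one record.

    Missing values are None in memory and rendered as ``"."``.  The
    predicted significance (CTPS) and reclassification rank (CTRR) are
    always missing when fewer than two valid assertions exist (CVNA < 2).
    """

    vid: str
    rsid: str
    cvcs: Union[OverallSignificance, str, None]
    cvsz: int
    cvna: int
    cvds: list[str]
    cval: str
    cvle: Optional[datetime.date]
    cvvt: str
    ctrs: float
    ctaa: Optional[float]
    ctps: Optional[OverallSignificance]
    ctrr: Optional[int]
    vcf_match: str

    #: Output column order (tab-separated table header).
    FIELDS = (
        "VID",
        "rsID",
        "CVCS",
        "CVSZ",
        "CVNA",
        "CVDS",
        "CVAL",
        "CVLE",
        "CVVT",
        "CTRS",
        "CTAA",
        "CTPS",
        "CTRR",
        "vcf_match",
    )

    def __post_init__(self) -> None:
        if self.cvna < 2 and (self.ctps is not None or self.ctrr is not None):
            raise ValueError("CTPS/CTRR must be missing when CVNA < 2")
        if self.ctrr is not None and self.ctrr not in (0, 1, 2, 3):
            raise ValueError(f"CTRR out of range: {self.ctrr}")

    def to_row(self) -> list[str]:
        """Render the 14 fields as strings, '.' for missing."""
        return [
            self.vid or MISSING,
            self.rsid or MISSING,
            format_significance(self.cvcs),
            str(self.cvsz),
            str(self.cvna),
            "|".join(self.cvds) if self.cvds else MISSING,
            self.cval or MISSING,
            self.cvle.isoformat() if self.cvle else MISSING,
            self.cvvt or MISSING,
            format_number(self.ctrs),
            format_number(self.ctaa) if self.ctaa is not None else MISSING,
            self.ctps.value if self.ctps is not None else MISSING,
            str(self.ctrr) if self.ctrr is not None else MISSING,
            self.vcf_match or MISSING,
        ]


def format_significance(sig: Union[OverallSignificance, str, None]) -> str:
    if sig is None:
        return MISSING
    if isinstance(sig, OverallSignificance):
        return sig.value
    return str(sig)


def format_number(x: float) -> str:
    """Compact decimal rendering: 24.903, 12, 1.666666667."""
    return f"{round(float(x), 9):.10g}"
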