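"""Synthetic variation records and packaged worked-example fixtures.

Two data sources live here:

* :func:`packaged_worked_examples` — the two published worked-example
  assertion sets (ten three-star uncertain-significance records predicted
  pathogenic, and sixteen conflicting-interpretation records with exactly
  two criteria-driven assertions), transcribed date-for-date, plus a small
  VCF whose ID column carries their rsIDs.  Assertion dates, significances
  and submitter tiers are as printed; chromosome positions and alleles in
  the toy VCF are fabricated (the source tables do not print them).

* :func:`generate_records` — a seeded generator of records with
  controllable class mix, assertion count/age distributions, submitter mix
  and label noise.  Defaults emulate the reported census moments of the
  curated database (≈3.3 ± 1.9 assertions per record, mean assertion age
  ≈1.5 ± 0.9 years); it does not emulate submitter ecology, condition
  ontologies, or per-gene structure.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np

from .model import (
    AssertionSignificance,
    ClinicalAssertion,
    OverallSignificance,
    SubmitterCategory,
    VariationRecord,
)

#: Date relative to which packaged fixtures and generated ages reproduce.
REFERENCE_DATE = datetime.date(2018, 6, 1)

_EP = SubmitterCategory.EXPERT_PANEL
_CP = SubmitterCategory.CRITERIA_PROVIDED
_NC = SubmitterCategory.NO_CRITERIA
_LIT = SubmitterCategory.LITERATURE_ONLY

# (vid, rsid, condition, [(date, significance), ...]); first assertion is the
# expert-panel review, the rest are criteria-provided clinical assertions.
_THREE_STAR_US = [
    ("38183", "81002812", "Hereditary cancer-predisposing syndrome",
     [("2016-04-15", "US"), ("2016-09-16", "P"), ("2017-08-18", "P"),
      ("2014-09-03", "LP"), ("2015-10-02", "P"), ("2016-03-01", "P")]),
    ("42965", "397516187", "Hypertrophic cardiomyopathy",
     [("2016-12-15", "US"), ("2014-05-13", "P"), ("2016-07-22", "LP"),
      ("2013-09-25", "LP"), ("2017-07-24", "LP")]),
    ("89172", "587779204", "Hereditary cancer-predisposing syndrome",
     [("2013-09-05", "US"), ("2017-08-30", "LP"), ("2017-07-07", "LP"),
      ("2017-05-15", "US"), ("2017-05-10", "US"), ("2016-05-17", "P")]),
    ("90099", "267607893", "Hereditary cancer-predisposing syndrome",
     [("2013-09-05", "US"), ("2015-07-02", "LP"), ("2016-07-05", "P")]),
    ("91028", "63751469", "Hereditary cancer-predisposing syndrome",
     [("2015-10-28", "US"), ("2017-06-09", "P"), ("2017-09-07", "LP")]),
    ("91030", "63750084", "Hereditary cancer-predisposing syndrome",
     [("2015-10-28", "US"), ("2014-05-27", "P"), ("2014-10-20", "P"),
      ("2017-07-14", "P")]),
    ("91033", "63750808", "Hereditary cancer-predisposing syndrome",
     [("2015-10-28", "US"), ("2017-08-17", "P"), ("2016-01-18", "LP")]),
    ("91035", "63751007", "Hereditary cancer-predisposing syndrome",
     [("2015-10-28", "US"), ("2014-06-20", "P"), ("2017-12-20", "P")]),
    ("91328", "267608161", "Hereditary cancer-predisposing syndrome",
     [("2013-09-05", "US"), ("2017-07-12", "LP"), ("2017-04-26", "P"),
      ("2017-12-05", "LP"), ("2016-03-25", "P")]),
    ("91330", "587779335", "Hereditary cancer-predisposing syndrome",
     [("2015-11-24", "US"), ("2017-11-21", "P"), ("2017-07-09", "P"),
      ("2014-10-30", "LP"), ("2016-07-14", "LB"), ("2017-03-27", "P")]),
]

# (vid, rsid, [(date, sig) x2 criteria-provided], [(date|None, sig, category)
# further assertions without criteria])
_CI_TWO_VALID = [
    ("10768", "199473684",
     [("2014-10-07", "P"), ("2018-01-02", "P")],
     [("2002-04-01", "US", _NC), ("2007-01-05", "P", _LIT)]),
    ("12348", "121912652",
     [("2016-05-23", "P"), ("2016-09-23", "P")],
     [(None, "US", _NC), ("1990-11-30", "P", _NC)]),
    ("18011", "121909551",
     [("2016-06-14", "P"), ("2018-01-19", "P")],
     [("1992-03-01", "US", _NC), ("2014-06-01", "LB", _NC)]),
    ("54153", "80357164",
     [("2015-10-02", "P"), ("2016-10-17", "LP")],
     [("2014-01-31", "US", _NC)]),
    ("55564", "80358073",
     [("2015-10-02", "P"), ("2015-09-21", "P")],
     [("2011-12-07", "P", _NC), ("1998-08-26", "US", _NC)]),
    ("93457", "61748906",
     [("2012-12-19", "P"), ("2017-06-30", "P")],
     [("2017-04-30", "LP", _NC), (None, "B", _NC)]),
    ("143603", "61748420",
     [("2013-02-08", "P"), ("2017-06-13", "P")],
     [("2011-02-15", "US", _NC)]),
    ("143738", "61749723",
     [("2016-11-16", "P"), ("2015-06-30", "LP")],
     [("2008-01-21", "US", _NC)]),
    ("156661", "587783132",
     [("2016-06-15", "P"), ("2015-09-11", "P")],
     [("2009-11-05", "US", _NC)]),
    ("161516", "193920774",
     [("2016-10-07", "LP"), ("2016-08-03", "P")],
     []),
    ("185705", "80356913",
     [("2017-06-26", "LP"), ("2015-10-02", "P")],
     [("2014-01-31", "US", _NC)]),
    ("201215", "794728721",
     [("2016-10-10", "P"), ("2017-05-03", "P")],
     [("2015-03-19", "LP", _NC), (None, "US", _NC)]),
    ("202509", "768431507",
     [("2017-08-07", "P"), ("2017-02-15", "LP")],
     [("2014-03-26", "US", _NC)]),
    ("203805", "150591260",
     [("2017-04-24", "P"), ("2017-05-05", "P")],
     [("2016-02-29", "P", _NC), ("2017-10-31", "US", _NC)]),
    ("205867", "796052621",
     [("2015-10-28", "P"), ("2016-06-13", "P")],
     [("2016-09-30", "US", _NC)]),
    ("280584", "886041761",
     [("2016-05-18", "P"), ("2017-02-14", "LP")],
     [("2016-12-31", "US", _NC)]),
]

_ALT_CYCLE = "ACGT"


def _date(text: Optional[str]) -> Optional[datetime.date]:
    return datetime.date.fromisoformat(text) if text else None


def _alt_for(index: int) -> str:
    return _ALT_CYCLE[index % 4]


def _ref_for(index: int) -> str:
    return _ALT_CYCLE[(index + 1) % 4]


def three_star_us_records() -> list[VariationRecord]:
    """Ten three-star uncertain-significance worked-example records."""
    records = []
    for i, (vid, rsid, condition, pairs) in enumerate(_THREE_STAR_US):
        assertions = [
            ClinicalAssertion(
                significance=AssertionSignificance(sig),
                last_evaluated=_date(date),
                submitter_category=_EP if j == 0 else _CP,
                submitter_name="expert panel" if j == 0 else f"clinical lab {j}",
                conditions=[condition],
            )
            for j, (date, sig) in enumerate(pairs)
        ]
        records.append(
            VariationRecord(
                vid=vid,
                rsids=[rsid],
                cvcs=OverallSignificance.US,
                stars=3,
                variant_type="Simple",
                alt_alleles=[_alt_for(i)],
                conditions=[condition],
                cv_last_evaluated=max(a.last_evaluated for a in assertions),
                assertions=assertions,
            )
        )
    return records


def conflicting_ci_records() -> list[VariationRecord]:
    """Sixteen conflicting-interpretation records, two valid assertions each."""
    records = []
    for i, (vid, rsid, valid, extra) in enumerate(_CI_TWO_VALID):
        assertions = [
            ClinicalAssertion(
                significance=AssertionSignificance(sig),
                last_evaluated=_date(date),
                submitter_category=_CP,
                submitter_name=f"clinical lab {j}",
            )
            for j, (date, sig) in enumerate(valid)
        ]
        assertions += [
            ClinicalAssertion(
                significance=AssertionSignificance(sig),
                last_evaluated=_date(date),
                submitter_category=cat,
                submitter_name="legacy submitter",
            )
            for date, sig, cat in extra
        ]
        records.append(
            VariationRecord(
                vid=vid,
                rsids=[rsid],
                cvcs=OverallSignificance.CI,
                stars=1,
                variant_type="Simple",
                alt_alleles=[_alt_for(i)],
                conditions=[],
                cv_last_evaluated=max(
                    (a.last_evaluated for a in assertions if a.last_evaluated),
                    default=None,
                ),
                assertions=assertions,
            )
        )
    return records


def toy_vcf_text() -> str:
    """A small VCF 4.3 body carrying the worked-example rsIDs.

    Positions and alleles are fabricated to pair with the fixture records;
    the last site carries an rsID absent from the fixtures and passes
    through unannotated.
    """
    lines = [
        "##fileformat=VCFv4.3",
        "##source=clinrank-toy",
        '##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    for i, (vid, rsid, _valid, _extra) in enumerate(_CI_TWO_VALID):
        lines.append(
            f"1\t{100000 + 10 * i}\trs{rsid}\t{_ref_for(i)}\t{_alt_for(i)}"
            f"\t50\tPASS\tDP={30 + i}"
        )
    lines.append("2\t900000\trs999999999\tA\tT\t50\tPASS\tDP=12")
    return "\n".join(lines) + "\n"


def packaged_worked_examples() -> tuple[list[VariationRecord], list[VariationRecord], str]:
    """(three-star records, conflicting-interpretation records, toy VCF text)."""
    return three_star_us_records(), conflicting_ci_records(), toy_vcf_text()


# --------------------------------------------------------------------------
# Seeded generator

_CLASSES = tuple(AssertionSignificance)


@dataclass(frozen=True)
class GeneratorSpec:
    """Stated world for synthetic record generation.

    Defaults reproduce the reported census moments: ≈3.3 ± 1.9 assertions
    per record (rounded normal, clipped to a minimum of two so every record
    is scoreable) and assertion ages with mean 1.5 y, sd 0.9 y (gamma).
    ``label_noise`` is the probability that one assertion's significance
    deviates a single step from the record's true class.
    """

    seed: int = 0
    n_records: int = 1000
    class_mix: Mapping[AssertionSignificance, float] = field(
        default_factory=lambda: {c: 0.2 for c in _CLASSES}
    )
    assertions_mean: float = 3.3
    assertions_sd: float = 1.9
    age_mean_years: float = 1.5
    age_sd_years: float = 0.9
    submitter_mix: Mapping[SubmitterCategory, float] = field(
        default_factory=lambda: {
            SubmitterCategory.CRITERIA_PROVIDED: 0.92,
            SubmitterCategory.EXPERT_PANEL: 0.03,
            SubmitterCategory.NO_CRITERIA: 0.03,
            SubmitterCategory.LITERATURE_ONLY: 0.02,
        }
    )
    label_noise: float = 0.1
    reference_date: datetime.date = REFERENCE_DATE

    def __post_init__(self) -> None:
        for mix in (self.class_mix, self.submitter_mix):
            total = sum(mix.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"mix proportions must sum to 1, got {total}")
        if not 0.0 <= self.label_noise <= 1.0:
            raise ValueError("label_noise must be a probability")


def _overall_from_assertions(
    sigs: list[AssertionSignificance], true_class: AssertionSignificance
) -> OverallSignificance:
    if not sigs:
        return OverallSignificance(true_class.value)
    labels = set(sigs)
    if len(labels) == 1:
        return OverallSignificance(labels.pop().value)
    zones = {
        "benign" if s.rank < 2 else "uncertain" if s.rank == 2 else "pathogenic"
        for s in labels
    }
    if zones == {"pathogenic"}:
        return OverallSignificance.PLP
    if zones == {"benign"}:
        return OverallSignificance.BLB
    return OverallSignificance.CI


def generate_records(
    spec: GeneratorSpec,
) -> list[tuple[VariationRecord, AssertionSignificance]]:
    """Seed-determined synthetic records, each paired with its true class.

    Stars follow assertion concordance: two stars for records whose
    criteria-based assertions agree (the calibration population), one star
    for conflicted or single-assertion records, zero otherwise.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.n_records <= 0:
        return []
    classes = list(spec.class_mix)
    class_p = np.array([spec.class_mix[c] for c in classes], dtype=float)
    cats = list(spec.submitter_mix)
    cat_p = np.array([spec.submitter_mix[c] for c in cats], dtype=float)
    age_shape = (spec.age_mean_years / spec.age_sd_years) ** 2
    age_scale = spec.age_mean_years / age_shape

    true_idx = rng.choice(len(classes), size=spec.n_records, p=class_p)
    counts = np.clip(
        np.rint(rng.normal(spec.assertions_mean, spec.assertions_sd, spec.n_records)),
        2,
        None,
    ).astype(int)

    out: list[tuple[VariationRecord, AssertionSignificance]] = []
    for i in range(spec.n_records):
        true_class = classes[true_idx[i]]
        k = int(counts[i])
        ages = rng.gamma(age_shape, age_scale, size=k)
        cat_draw = rng.choice(len(cats), size=k, p=cat_p)
        noise = rng.random(k) < spec.label_noise
        direction = rng.integers(0, 2, size=k) * 2 - 1
        assertions = []
        valid_sigs = []
        for j in range(k):
            rank = true_class.rank
            if noise[j]:
                rank = min(4, max(0, rank + int(direction[j])))
            sig = _CLASSES[rank]
            date = spec.reference_date - datetime.timedelta(
                days=int(round(ages[j] * 365.25))
            )
            cat = cats[cat_draw[j]]
            assertions.append(
                ClinicalAssertion(
                    significance=sig,
                    last_evaluated=date,
                    submitter_category=cat,
                    submitter_name=f"synthetic lab {j}",
                )
            )
            if cat in (
                SubmitterCategory.CRITERIA_PROVIDED,
                SubmitterCategory.EXPERT_PANEL,
                SubmitterCategory.PRACTICE_GUIDELINE,
            ):
                valid_sigs.append(sig)
        cvcs = _overall_from_assertions(valid_sigs, true_class)
        if len(valid_sigs) >= 2 and len(set(valid_sigs)) == 1:
            stars = 2
        elif len(valid_sigs) >= 2 and cvcs in (
            OverallSignificance.BLB,
            OverallSignificance.PLP,
        ):
            stars = 2
        elif valid_sigs:
            stars = 1
        else:
            stars = 0
        rec = VariationRecord(
            vid=str(900000 + i),
            rsids=[str(990000000 + i)],
            cvcs=cvcs,
            stars=stars,
            variant_type="Simple",
            alt_alleles=[_alt_for(i)],
            conditions=[f"synthetic condition {i % 7}"],
            cv_last_evaluated=max(a.last_evaluated for a in assertions),
            assertions=assertions,
        )
        out.append((rec, true_class))
    return out
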