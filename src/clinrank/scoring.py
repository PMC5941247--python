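"""Weighted aggregation of clinical assertions into the raw score (CTRS).

Each valid assertion *i* contributes the product of three factors::

    CTRS = sum_i  x_i * d_i * s_i

``x_i`` — significance weight: B=-6, LB=-3, US=-0.3, LP=+3, P=+6.  The
pairs B/P and LB/LP are antisymmetric and full classes weigh twice their
"likely" neighbours, so an assertion decayed to half strength is effectively
downgraded one tier.

``d_i`` — age decay on the whole years *n* since the assertion was last
evaluated: no penalty for the first two years, then a 10% reduction per
year through year six, then a flat 50%::

    d = 1          (n < 2)
    d = (11-n)/10  (2 <= n <= 6)
    d = 0.5        (n > 6)

``s_i`` — submitter tier: practice guideline 1.25, expert panel 1.10,
criteria-provided clinical testing 1.00, everything else 0 (and such
assertions are excluded up front as invalid).

CTAA is the mean whole-year age of the valid assertions; CVNA their count.
"""

from __future__ import annotations

import datetime
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

from .model import (
    AssertionSignificance,
    ClinicalAssertion,
    SubmitterCategory,
    is_valid_assertion,
)

logger = logging.getLogger(__name__)

#: Mean tropical-year length; ages are floor(days / DAYS_PER_YEAR).
DAYS_PER_YEAR = 365.25


@dataclass(frozen=True)
class ScoringConstants:
    """The weight tables; defaults are the shipped calibration."""

    assertion_weights: Mapping[AssertionSignificance, float] = field(
        default_factory=lambda: {
            AssertionSignificance.B: -6.0,
            AssertionSignificance.LB: -3.0,
            AssertionSignificance.US: -0.3,
            AssertionSignificance.LP: 3.0,
            AssertionSignificance.P: 6.0,
        }
    )
    age_grace_years: int = 2
    age_floor_factor: float = 0.5
    submitter_factors: Mapping[SubmitterCategory, float] = field(
        default_factory=lambda: {
            SubmitterCategory.PRACTICE_GUIDELINE: 1.25,
            SubmitterCategory.EXPERT_PANEL: 1.10,
            SubmitterCategory.CRITERIA_PROVIDED: 1.00,
        }
    )


DEFAULT_CONSTANTS = ScoringConstants()


@dataclass(frozen=True)
class EvaluationContext:
    """Pins the date at which assertion ages are measured.

    Defaults to today, matching interactive use; analyses meant to be
    reproducible should pin an explicit date.
    """

    evaluation_date: datetime.date = field(default_factory=datetime.date.today)
    constants: ScoringConstants = DEFAULT_CONSTANTS


def assertion_weight(
    sig: AssertionSignificance, constants: ScoringConstants = DEFAULT_CONSTANTS
) -> float:
    """Significance weight x_i for one of the five Mendelian labels."""
    try:
        return constants.assertion_weights[sig]
    except KeyError:
        raise ValueError(f"no assertion weight defined for {sig!r}") from None


def age_years(last_evaluated: datetime.date, ctx: EvaluationContext) -> int:
    """Whole elapsed years between last evaluation and the context date.

    Computed as floor(days / 365.25); future-dated assertions clamp to 0
    with a warning (the record, not the clock, is presumed wrong).
    """
    days = (ctx.evaluation_date - last_evaluated).days
    if days < 0:
        logger.warning(
            "assertion dated %s is after evaluation date %s; treating age as 0",
            last_evaluated,
            ctx.evaluation_date,
        )
        return 0
    return int(days / DAYS_PER_YEAR)


def age_factor(n: int, constants: ScoringConstants = DEFAULT_CONSTANTS) -> float:
    """Age decay d_i for a whole-year age n >= 0."""
    if n < 0:
        raise ValueError("age must be non-negative")
    if n < constants.age_grace_years:
        return 1.0
    if n <= 6:
        return (11 - n) / 10.0
    return constants.age_floor_factor


def submitter_factor(
    c: SubmitterCategory, constants: ScoringConstants = DEFAULT_CONSTANTS
) -> float:
    """Submitter tier s_i; 0 for categories without assertion criteria."""
    return constants.submitter_factors.get(c, 0.0)


def assertion_contribution(a: ClinicalAssertion, ctx: EvaluationContext) -> float:
    """x_i * d_i * s_i for one assertion; 0 if the assertion is invalid."""
    if not is_valid_assertion(a):
        return 0.0
    return (
        assertion_weight(a.significance, ctx.constants)
        * age_factor(age_years(a.last_evaluated, ctx), ctx.constants)
        * submitter_factor(a.submitter_category, ctx.constants)
    )


def compute_ctrs(assertions: Iterable[ClinicalAssertion], ctx: EvaluationContext) -> float:
    """Raw score: sum of weighted valid assertions (0 for an empty list)."""
    return sum(assertion_contribution(a, ctx) for a in assertions)


def compute_ctaa(
    assertions: Iterable[ClinicalAssertion], ctx: EvaluationContext
) -> Optional[float]:
    """Mean whole-year age of valid assertions; None if there are none."""
    ages = [age_years(a.last_evaluated, ctx) for a in assertions if is_valid_assertion(a)]
    if not ages:
        return None
    return sum(ages) / len(ages)


def count_valid(assertions: Iterable[ClinicalAssertion]) -> int:
    """CVNA: number of assertions that pass the validity filter."""
    return sum(1 for a in assertions if is_valid_assertion(a))
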