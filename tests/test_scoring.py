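"""Scoring factors and aggregate score/age metrics against brute-force oracles."""

import datetime

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import clinrank as cr
from clinrank.scoring import DAYS_PER_YEAR, assertion_contribution

from conftest import PINNED_DATE, make_assertion

CTX = cr.EvaluationContext(evaluation_date=PINNED_DATE)
CP = cr.SubmitterCategory.CRITERIA_PROVIDED


@pytest.mark.parametrize(
    "sig, weight",
    [("B", -6.0), ("LB", -3.0), ("US", -0.3), ("LP", 3.0), ("P", 6.0)],
)
def test_assertion_weights(sig, weight):
    assert cr.assertion_weight(cr.AssertionSignificance(sig)) == weight


def test_weight_structure():
    """B/P and LB/LP antisymmetric; |US| < |LB| < |B|."""
    w = {s: cr.assertion_weight(s) for s in cr.AssertionSignificance}
    A = cr.AssertionSignificance
    assert w[A.B] == -w[A.P] and w[A.LB] == -w[A.LP]
    assert abs(w[A.US]) < abs(w[A.LB]) < abs(w[A.B])


@pytest.mark.parametrize(
    "date, expected",
    [
        (datetime.date(2016, 5, 23), 2),
        (datetime.date(2018, 1, 19), 0),
        (PINNED_DATE, 0),  # same-day
        (datetime.date(2018, 12, 1), 0),  # future-dated clamps to 0
    ],
)
def test_age_years(date, expected):
    assert cr.age_years(date, CTX) == expected


@given(days=st.integers(min_value=0, max_value=15000))
def test_age_years_matches_day_count_oracle(days):
    date = PINNED_DATE - datetime.timedelta(days=days)
    assert cr.age_years(date, CTX) == int(days // DAYS_PER_YEAR)


@pytest.mark.parametrize(
    "years, factor",
    [(0, 1.0), (1, 1.0), (2, 0.9), (3, 0.8), (4, 0.7), (5, 0.6), (6, 0.5),
     (7, 0.5), (9, 0.5), (50, 0.5)],
)
def test_age_factor(years, factor):
    assert cr.age_factor(years) == pytest.approx(factor)


def test_age_factor_non_increasing():
    factors = [cr.age_factor(n) for n in range(30)]
    assert all(a >= b for a, b in zip(factors, factors[1:]))
    assert all(0.5 <= f <= 1.0 for f in factors)


@pytest.mark.parametrize(
    "category, factor",
    [
        (cr.SubmitterCategory.PRACTICE_GUIDELINE, 1.25),
        (cr.SubmitterCategory.EXPERT_PANEL, 1.10),
        (cr.SubmitterCategory.CRITERIA_PROVIDED, 1.00),
        (cr.SubmitterCategory.NO_CRITERIA, 0.0),
        (cr.SubmitterCategory.LITERATURE_ONLY, 0.0),
    ],
)
def test_submitter_factor(category, factor):
    assert cr.submitter_factor(category) == factor


def test_unknown_significance_weight_errors():
    with pytest.raises(ValueError):
        cr.assertion_weight("Pathogenic")  # not an enum member


# ---------------------------------------------------------------------------
# Aggregates

def test_ctrs_empty_and_invalid_only():
    assert cr.compute_ctrs([], CTX) == 0.0
    invalid = [make_assertion(category=cr.SubmitterCategory.NO_CRITERIA)]
    assert cr.compute_ctrs(invalid, CTX) == 0.0
    assert cr.compute_ctaa(invalid, CTX) is None
    assert cr.count_valid(invalid) == 0


_assertions = st.lists(
    st.builds(
        cr.ClinicalAssertion,
        significance=st.one_of(st.none(), st.sampled_from(list(cr.AssertionSignificance))),
        last_evaluated=st.one_of(
            st.none(),
            st.dates(datetime.date(1990, 1, 1), datetime.date(2018, 6, 1)),
        ),
        submitter_category=st.sampled_from(list(cr.SubmitterCategory)),
    ),
    max_size=12,
)


def _brute_force_ctrs(assertions):
    """Independent enumeration: multiply the three factors per assertion."""
    weights = {"B": -6, "LB": -3, "US": -0.3, "LP": 3, "P": 6}
    tiers = {"practice_guideline": 1.25, "expert_panel": 1.10, "criteria_provided": 1.0}
    total = 0.0
    for a in assertions:
        if a.significance is None or a.last_evaluated is None:
            continue
        s = tiers.get(a.submitter_category.value, 0.0)
        if s == 0.0:
            continue
        n = max((PINNED_DATE - a.last_evaluated).days, 0) // 365.25
        n = int(n)
        d = 1.0 if n < 2 else ((11 - n) / 10.0 if n <= 6 else 0.5)
        total += weights[a.significance.value] * d * s
    return total


@settings(max_examples=300, deadline=None)
@given(assertions=_assertions)
def test_ctrs_matches_brute_force_oracle(assertions):
    assert cr.compute_ctrs(assertions, CTX) == pytest.approx(
        _brute_force_ctrs(assertions)
    )


@settings(max_examples=200, deadline=None)
@given(assertions=_assertions)
def test_ctaa_bounded_by_extreme_ages(assertions):
    ages = [
        cr.age_years(a.last_evaluated, CTX)
        for a in assertions
        if cr.is_valid_assertion(a)
    ]
    ctaa = cr.compute_ctaa(assertions, CTX)
    if not ages:
        assert ctaa is None
    else:
        assert min(ages) <= ctaa <= max(ages)


@settings(max_examples=100, deadline=None)
@given(assertions=_assertions)
def test_young_full_class_assertion_shifts_score_exactly(assertions):
    """A fresh valid P adds exactly +6; a fresh valid B exactly -6."""
    base = cr.compute_ctrs(assertions, CTX)
    young = PINNED_DATE - datetime.timedelta(days=100)
    plus = assertions + [make_assertion(sig="P", date=young)]
    minus = assertions + [make_assertion(sig="B", date=young)]
    assert cr.compute_ctrs(plus, CTX) == pytest.approx(base + 6.0)
    assert cr.compute_ctrs(minus, CTX) == pytest.approx(base - 6.0)


@settings(max_examples=100, deadline=None)
@given(
    sig=st.sampled_from(list(cr.AssertionSignificance)),
    days=st.integers(min_value=0, max_value=10000),
    advance=st.integers(min_value=0, max_value=3000),
)
def test_contribution_decays_without_sign_change(sig, days, advance):
    """|contribution| never grows as the evaluation date advances."""
    a = make_assertion(sig=sig.value, date=PINNED_DATE - datetime.timedelta(days=days))
    later = cr.EvaluationContext(
        evaluation_date=PINNED_DATE + datetime.timedelta(days=advance)
    )
    now_c = assertion_contribution(a, CTX)
    later_c = assertion_contribution(a, later)
    assert abs(later_c) <= abs(now_c) + 1e-12
    assert now_c * later_c >= 0


# ---------------------------------------------------------------------------
# Worked examples (printed per-variant data)

def test_worked_example_six_assertion_record(three_star_records):
    rec = next(r for r in three_star_records if r.vid == "38183")
    assert cr.count_valid(rec.assertions) == 6
    assert cr.compute_ctrs(rec.assertions, CTX) == pytest.approx(24.903)
    assert cr.compute_ctaa(rec.assertions, CTX) == pytest.approx(10 / 6)


def test_worked_example_two_valid_two_invalid(ci_records):
    rec = next(r for r in ci_records if r.vid == "12348")
    assert cr.count_valid(rec.assertions) == 2  # the no-criteria pair is excluded
    assert cr.compute_ctrs(rec.assertions, CTX) == pytest.approx(11.4)
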