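import datetime

import pytest

import clinrank as cr

#: Date at which the packaged worked-example metrics reproduce.
PINNED_DATE = datetime.date(2018, 6, 1)


@pytest.fixture(scope="session")
def ctx():
    return cr.EvaluationContext(evaluation_date=PINNED_DATE)


@pytest.fixture(scope="session")
def ranges():
    return cr.default_ranges()


@pytest.fixture(scope="session")
def three_star_records():
    return cr.three_star_us_records()


@pytest.fixture(scope="session")
def ci_records():
    return cr.conflicting_ci_records()


@pytest.fixture()
def records_file(tmp_path, three_star_records, ci_records):
    path = tmp_path / "records.jsonl"
    cr.write_fixture_records(three_star_records + ci_records, path)
    return path


@pytest.fixture()
def toy_vcf(tmp_path):
    path = tmp_path / "toy.vcf"
    path.write_text(cr.toy_vcf_text())
    return path


def make_assertion(
    sig="P",
    date=datetime.date(2017, 6, 1),
    category=cr.SubmitterCategory.CRITERIA_PROVIDED,
):
    return cr.ClinicalAssertion(
        significance=cr.AssertionSignificance(sig) if sig else None,
        last_evaluated=date,
        submitter_category=category,
    )
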