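import pytest

from candykano.survey_io import (
    ResponseRecord,
    ResponseSet,
    ServiceItem,
    fixture_catalog,
    get_fixture,
)
from candykano.candy_core import SatisfactionProfile


@pytest.fixture(scope="session")
def table9():
    return get_fixture("profiles_table9")


@pytest.fixture(scope="session")
def profile9(table9) -> SatisfactionProfile:
    return SatisfactionProfile.from_table(table9)


@pytest.fixture(scope="session")
def catalog46():
    return fixture_catalog()


@pytest.fixture
def tiny_catalog():
    return [
        ServiceItem("A1", "meals", "life"),
        ServiceItem("B1", "call device", "intelligent"),
        ServiceItem("C1", "checkups", "health"),
    ]


def make_record(rid, codes, forward, reverse, importance=None, demographics=None):
    """Build a record from parallel per-item answer lists."""
    importance = importance or [3] * len(codes)
    return ResponseRecord(
        respondent_id=rid,
        forward=dict(zip(codes, forward)),
        reverse=dict(zip(codes, reverse)),
        importance=dict(zip(codes, importance)),
        demographics=demographics or {},
    )


@pytest.fixture
def tiny_rs(tiny_catalog):
    """3 items x 4 respondents, complete answers, two demographic groups."""
    codes = [it.code for it in tiny_catalog]
    records = [
        make_record("r1", codes, [5, 4, 3], [1, 2, 3], [5, 4, 3], {"sex": "f"}),
        make_record("r2", codes, [5, 3, 2], [1, 3, 4], [5, 3, 2], {"sex": "f"}),
        make_record("r3", codes, [4, 4, 3], [2, 2, 3], [4, 4, 3], {"sex": "m"}),
        make_record("r4", codes, [3, 5, 4], [3, 1, 2], [3, 5, 4], {"sex": "m"}),
    ]
    return ResponseSet(catalog=tiny_catalog, records=records)
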