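import pytest

from agrorules import profile_from_thresholds
from agrorules.zones import GUINEAN, SUDANIAN, SUDANO_GUINEAN, ZONE_THRESHOLDS

#: classic five-transaction basket used for hand-verifiable mining examples
SMALL_DB = [
    frozenset("ab"),
    frozenset("bc"),
    frozenset("abc"),
    frozenset("b"),
    frozenset("ac"),
]


@pytest.fixture
def small_db():
    return list(SMALL_DB)


@pytest.fixture(scope="session")
def sudanian_profile():
    return profile_from_thresholds(SUDANIAN)


@pytest.fixture(scope="session")
def all_profiles():
    return [profile_from_thresholds(t)
            for t in (SUDANIAN, SUDANO_GUINEAN, GUINEAN)]


@pytest.fixture(scope="session")
def zone_tables():
    return ZONE_THRESHOLDS
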