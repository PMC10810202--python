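import pytest

from cenrec import (
    CentromereBreakpointMapper,
    IsolateClassifier,
    cen3_fixture_pair,
    find_informative_sites,
    gen_roster,
)

CEN3_POSITIONS = (11, 13, 24, 68, 70, 81, 101)


@pytest.fixture(scope="session")
def cen3_pair():
    return cen3_fixture_pair()


@pytest.fixture(scope="session")
def cen3_sites(cen3_pair):
    return find_informative_sites(cen3_pair)


@pytest.fixture(scope="session")
def cen3_mapper(cen3_pair):
    return CentromereBreakpointMapper().fit(cen3_pair)


@pytest.fixture(scope="session")
def canonical_roster():
    isolates, truth = gen_roster(seed=42)
    return isolates, truth


@pytest.fixture(scope="session")
def canonical_results(canonical_roster):
    isolates, _ = canonical_roster
    return IsolateClassifier().fit().predict(isolates)
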