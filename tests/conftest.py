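from datetime import date

import pytest

from oncomop import (
    CdmStore,
    ConceptGraph,
    Concept,
    Person,
    integrate_all,
    make_fig3_vocab,
    make_fixture_vocab,
    precoordinate,
)
from oncomop import concepts as C

WORKED_CODES = ["8520/3-C50.9", "8010/3-C50.9"]


@pytest.fixture
def fig3_graph() -> ConceptGraph:
    return make_fig3_vocab()


@pytest.fixture
def fixture_graph() -> ConceptGraph:
    return make_fixture_vocab()


@pytest.fixture
def integrated_graph(fixture_graph) -> ConceptGraph:
    """Full fixture vocabulary with the two worked-example codes
    precoordinated and integrated."""
    precoordinate(WORKED_CODES, fixture_graph)
    integrate_all(fixture_graph, WORKED_CODES)
    return fixture_graph


@pytest.fixture
def store(integrated_graph) -> CdmStore:
    s = CdmStore(integrated_graph)
    s.add_person(Person(1, C.GENDER_FEMALE, 1960))
    s.add_person(Person(2, C.GENDER_MALE, 1955))
    return s


def chain_graph(codes: list[str]) -> ConceptGraph:
    """A -> B -> C ... 'Is a' chain of bare concepts for hierarchy tests."""
    g = ConceptGraph()
    for i, code in enumerate(codes):
        g.add_concept(
            Concept(i + 1, code, "Condition", "SNOMED", "Disorder", code, True)
        )
    for i in range(len(codes) - 1):
        g.add_relationship(i + 1, i + 2, "Is a")
    return g


D0 = date(2020, 1, 1)


def day(n: int) -> date:
    from datetime import timedelta

    return D0 + timedelta(days=n)
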