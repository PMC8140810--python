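"""Precoordination of ICD-O-3 cancer diagnoses and their integration into a
SNOMED-style disease hierarchy.

An ICD-O-3 diagnosis is the triple (histology, behavior, topography), written
``HHHH/B-Cnn.n`` (e.g. ``8520/3-C50.9``, lobular carcinoma NOS of breast NOS).
Only observed triples are instantiated as single Condition concepts
("precoordination").  Each precoordinated concept is then integrated in two
steps:

1. *Attribute resolution* — the histology/behavior pair and the topography
   are translated, through ``Maps to`` equivalences, into the SNOMED
   *associated morphology* and *finding site* attributes.
2. *Equivalence or insertion* — if an existing disorder sits at exactly that
   (morphology, finding site) intersection, the ICD-O concept is mapped to it
   and the disorder stays the standard concept.  Otherwise the ICD-O concept
   itself becomes a standard disorder, receives the two attribute edges, and
   is placed in the hierarchy as a child of the most specific disorder(s)
   whose attributes subsume the intersection.

Insertion preserves every pre-existing ancestor/descendant pair, so cohort
queries written against the original hierarchy keep working unchanged.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from . import concepts as C
from .errors import MappingError, VocabularyError
from .vocab_store import Concept, ConceptGraph, Rel, rebuild_ancestors

logger = logging.getLogger(__name__)

_ICDO_RE = re.compile(r"^(\d{4})/(\d)-(C\d{2}(?:\.\d)?)$")

MODE_EQUIVALENT = "EQUIVALENT"
MODE_INSERTED = "INSERTED"


@dataclass(frozen=True)
class IcdoCode:
    """Parsed ICD-O-3 triple; ``combined_code`` round-trips to the parts."""

    histology: str  # 4 digits, 8000-9999
    behavior: str  # one of 0,1,2,3
    topography: str  # Cnn or Cnn.n

    @property
    def combined_code(self) -> str:
        return f"{self.histology}/{self.behavior}-{self.topography}"

    @property
    def histology_behavior(self) -> str:
        return f"{self.histology}/{self.behavior}"

    @property
    def topography_prefix(self) -> str:
        return self.topography.split(".")[0]


@dataclass(frozen=True)
class AttributePair:
    """The two SNOMED defining attributes of a cancer disorder."""

    morphology_concept_id: int
    finding_site_concept_id: int


@dataclass(frozen=True)
class IntegrationOutcome:
    icdo_concept_id: int
    mode: str  # EQUIVALENT or INSERTED
    standard_concept_id: int
    parent_concept_ids: tuple[int, ...] = ()


def parse_icdo(code: str) -> IcdoCode:
    """Parse ``HHHH/B-Cnn.n`` into an :class:`IcdoCode`.

    Histology must lie in 8000-9999 and behavior in {0,1,2,3}.
    """
    m = _ICDO_RE.match(code.strip())
    if m is None:
        raise MappingError(f"malformed ICD-O-3 code {code!r}")
    histology, behavior, topography = m.groups()
    if not 8000 <= int(histology) <= 9999:
        raise MappingError(
            f"malformed ICD-O-3 code {code!r}: histology {histology} "
            "outside 8000-9999"
        )
    if behavior not in "0123":
        raise MappingError(
            f"malformed ICD-O-3 code {code!r}: behavior {behavior} "
            "not in 0-3"
        )
    return IcdoCode(histology, behavior, topography)


def _as_icdo(code: str | IcdoCode) -> IcdoCode:
    return code if isinstance(code, IcdoCode) else parse_icdo(code)


def precoordinate(
    observed_combinations: Iterable[str | IcdoCode], graph: ConceptGraph
) -> ConceptGraph:
    """Create one Condition concept per unique observed ICD-O-3 triple.

    Combinations never observed are not instantiated.  Each new concept gets
    ``Has Histology`` / ``Has Topography`` edges to its component concepts;
    ids are minted in sorted combined-code order for determinism.  A triple
    whose components are missing from the vocabulary is a hard error.
    """
    codes = sorted(
        {_as_icdo(c).combined_code: _as_icdo(c) for c in observed_combinations}
        .values(),
        key=lambda c: c.combined_code,
    )
    for icdo in codes:
        hist = graph.by_code("ICDO3", icdo.histology_behavior)
        if hist is None:
            raise MappingError(
                f"histology concept {icdo.histology_behavior!r} missing from "
                f"vocabulary (code {icdo.combined_code})"
            )
        topo = graph.by_code("ICDO3", icdo.topography)
        if topo is None:
            raise MappingError(
                f"topography concept {icdo.topography!r} missing from "
                f"vocabulary (code {icdo.combined_code})"
            )
        if graph.by_code("ICDO3", icdo.combined_code) is not None:
            continue
        concept = graph.add_concept(
            Concept(
                concept_id=graph.new_concept_id(),
                concept_name=f"{hist.concept_name} of {topo.concept_name}",
                domain_id="Condition",
                vocabulary_id="ICDO3",
                concept_class_id="ICDO Condition",
                concept_code=icdo.combined_code,
                standard=False,
            )
        )
        graph.add_relationship(concept.concept_id, hist.concept_id, Rel.HAS_HISTOLOGY)
        graph.add_relationship(
            concept.concept_id, topo.concept_id, Rel.HAS_TOPOGRAPHY
        )
    return graph


def resolve_attributes(icdo: str | IcdoCode, graph: ConceptGraph) -> AttributePair:
    """Step 1: translate the ICD-O histology/behavior and topography into
    the equivalent SNOMED morphology and finding-site concepts."""
    icdo = _as_icdo(icdo)
    hist = graph.by_code("ICDO3", icdo.histology_behavior)
    if hist is None or not graph.targets(hist.concept_id, Rel.MAPS_TO):
        raise MappingError(
            f"no morphology equivalence for histology axis "
            f"{icdo.histology_behavior!r}"
        )
    topo = graph.by_code("ICDO3", icdo.topography)
    if topo is None or not graph.targets(topo.concept_id, Rel.MAPS_TO):
        raise MappingError(
            f"no finding-site equivalence for topography axis "
            f"{icdo.topography!r}"
        )
    morphology = min(graph.targets(hist.concept_id, Rel.MAPS_TO))
    site = min(graph.targets(topo.concept_id, Rel.MAPS_TO))
    return AttributePair(morphology, site)


def _disorder_attributes(graph: ConceptGraph, concept_id: int) -> AttributePair | None:
    morphs = graph.targets(concept_id, Rel.HAS_ASSOC_MORPH)
    sites = graph.targets(concept_id, Rel.HAS_FINDING_SITE)
    if not morphs or not sites:
        return None
    return AttributePair(min(morphs), min(sites))


def _attributed_disorders(
    graph: ConceptGraph, exclude: frozenset[int] = frozenset()
) -> list[tuple[int, AttributePair]]:
    out = []
    for c in graph.concepts():
        if c.domain_id != "Condition" or not c.standard:
            continue
        if c.concept_id in exclude:
            continue
        pair = _disorder_attributes(graph, c.concept_id)
        if pair is not None:
            out.append((c.concept_id, pair))
    out.sort(key=lambda t: t[0])
    return out


def find_equivalent(
    pair: AttributePair,
    graph: ConceptGraph,
    exclude: Iterable[int] = (),
) -> int | None:
    """Step 2a: a standard disorder whose morphology AND finding site equal
    the pair exactly, or ``None``.  Several exact matches (the hierarchy
    assumes at most one) are resolved to the lowest concept id with a
    warning."""
    matches = [
        cid
        for cid, attrs in _attributed_disorders(graph, frozenset(exclude))
        if attrs == pair
    ]
    if not matches:
        return None
    if len(matches) > 1:
        logger.warning(
            "multiple exact attribute matches %s; choosing %s",
            matches,
            matches[0],
        )
    return matches[0]


def insert_into_hierarchy(
    icdo_concept_id: int,
    pair: AttributePair,
    graph: ConceptGraph,
    fallback_root: int = C.NEOPLASTIC_DISEASE,
) -> IntegrationOutcome:
    """Step 2b: make the ICD-O concept a standard disorder at the attribute
    intersection and hang it under the most specific subsuming disorder(s).

    A disorder subsumes the intersection when its morphology attribute is an
    ancestor-or-equal of ``pair.morphology`` and its site attribute an
    ancestor-or-equal of ``pair.finding_site``; non-minimal subsumers (those
    with a more specific subsumer below them) are pruned.  Multiple minimal
    parents are allowed (polyhierarchy).  If nothing subsumes, the configured
    root is used and a warning logged.
    """
    graph.concept(icdo_concept_id)
    graph.add_relationship(icdo_concept_id, pair.morphology_concept_id, Rel.HAS_ASSOC_MORPH)
    graph.add_relationship(
        icdo_concept_id, pair.finding_site_concept_id, Rel.HAS_FINDING_SITE
    )

    morph_ancestors = graph.ancestors_of(pair.morphology_concept_id)
    site_ancestors = graph.ancestors_of(pair.finding_site_concept_id)
    candidates = [
        (cid, attrs)
        for cid, attrs in _attributed_disorders(graph, frozenset({icdo_concept_id}))
        if attrs.morphology_concept_id in morph_ancestors
        and attrs.finding_site_concept_id in site_ancestors
    ]

    def _more_specific(y: tuple[int, AttributePair], x: tuple[int, AttributePair]) -> bool:
        """y is strictly more specific than x (by attributes or hierarchy)."""
        yid, ya = y
        xid, xa = x
        if xid in graph.ancestors_of(yid) and xid != yid:
            return True
        return (
            xa.morphology_concept_id in graph.ancestors_of(ya.morphology_concept_id)
            and xa.finding_site_concept_id
            in graph.ancestors_of(ya.finding_site_concept_id)
            and xa != ya
        )

    minimal = [
        x for x in candidates if not any(_more_specific(y, x) for y in candidates)
    ]
    if minimal:
        parents = tuple(sorted(cid for cid, _ in minimal))
    else:
        logger.warning(
            "no subsuming disorder for concept %s; defaulting to root %s",
            icdo_concept_id,
            fallback_root,
        )
        parents = (fallback_root,)

    graph.set_standard(icdo_concept_id, True)
    for parent in parents:
        graph.add_relationship(icdo_concept_id, parent, Rel.IS_A)
    rebuild_ancestors(graph)
    return IntegrationOutcome(
        icdo_concept_id, MODE_INSERTED, icdo_concept_id, parents
    )


def integrate(
    icdo_concept_id: int,
    graph: ConceptGraph,
    fallback_root: int = C.NEOPLASTIC_DISEASE,
) -> IntegrationOutcome:
    """Run the two-step integration for one precoordinated concept.

    Idempotent: a concept that already carries a ``Maps to`` edge, or that
    was already inserted as a standard disorder, yields its prior outcome
    without modifying the graph.
    """
    concept = graph.concept(icdo_concept_id)
    existing = graph.targets(icdo_concept_id, Rel.MAPS_TO)
    if existing:
        return IntegrationOutcome(
            icdo_concept_id, MODE_EQUIVALENT, min(existing)
        )
    parents = graph.targets(icdo_concept_id, Rel.IS_A)
    if concept.standard and parents:
        return IntegrationOutcome(
            icdo_concept_id, MODE_INSERTED, icdo_concept_id, tuple(sorted(parents))
        )

    pair = resolve_attributes(parse_icdo(concept.concept_code), graph)
    match = find_equivalent(pair, graph, exclude={icdo_concept_id})
    if match is not None:
        graph.add_relationship(icdo_concept_id, match, Rel.MAPS_TO)
        return IntegrationOutcome(icdo_concept_id, MODE_EQUIVALENT, match)
    return insert_into_hierarchy(icdo_concept_id, pair, graph, fallback_root)


def link_cancer_type(
    icdo_concept_id: int,
    graph: ConceptGraph,
    type_rules: Mapping[str, int],
) -> ConceptGraph:
    """Link a precoordinated diagnosis to its cancer type by topography
    prefix (e.g. any C50.* to the breast cancer type)."""
    concept = graph.concept(icdo_concept_id)
    icdo = parse_icdo(concept.concept_code)
    type_id = type_rules.get(icdo.topography_prefix)
    if type_id is None:
        logger.warning(
            "no cancer-type rule for topography prefix %s (concept %s)",
            icdo.topography_prefix,
            icdo_concept_id,
        )
        return graph
    graph.add_relationship(icdo_concept_id, type_id, Rel.HAS_CANCER_TYPE)
    return graph


def integrate_all(
    graph: ConceptGraph,
    codes: Sequence[str] | None = None,
    type_rules: Mapping[str, int] | None = None,
    fallback_root: int = C.NEOPLASTIC_DISEASE,
) -> list[IntegrationOutcome]:
    """Integrate every precoordinated concept (or the given codes) and,
    when rules are supplied, link cancer types.  Returns outcomes in
    combined-code order."""
    if codes is None:
        targets = sorted(
            (
                c
                for c in graph.concepts()
                if c.vocabulary_id == "ICDO3" and "-" in c.concept_code
            ),
            key=lambda c: c.concept_code,
        )
    else:
        targets = []
        for code in sorted(codes):
            c = graph.by_code("ICDO3", code)
            if c is None:
                raise VocabularyError(f"no precoordinated concept for {code!r}")
            targets.append(c)
    outcomes = []
    for c in targets:
        outcome = integrate(c.concept_id, graph, fallback_root)
        if type_rules is not None:
            link_cancer_type(c.concept_id, graph, type_rules)
        outcomes.append(outcome)
    return outcomes


def integration_report(
    outcomes: Iterable[IntegrationOutcome], graph: ConceptGraph
) -> pd.DataFrame:
    """Tabular report: icdo_code, mode, standard_concept_id, parents."""
    rows = [
        {
            "icdo_code": graph.concept(o.icdo_concept_id).concept_code,
            "mode": o.mode,
            "standard_concept_id": o.standard_concept_id,
            "parents": ";".join(str(p) for p in o.parent_concept_ids),
        }
        for o in outcomes
    ]
    return pd.DataFrame(rows, columns=["icdo_code", "mode", "standard_concept_id", "parents"])
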