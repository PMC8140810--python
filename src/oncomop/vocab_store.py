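"""Vocabulary layer: concepts, typed relationships, and the ancestor closure.

The store reads and writes the OMOP Standardized Vocabularies file dialect
(tab-delimited, upper-case column headers, ``S``/empty for the standard
flag) so that real vocabulary exports can be dropped in.  The hierarchical
ancestor closure is derived from ``Is a`` relationships and kept as explicit
(ancestor, descendant, min_levels, max_levels) rows, which is what makes
descendant-expanding cohort queries work unchanged after new concepts are
inserted into the hierarchy.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import networkx as nx

from .errors import VocabularyError

logger = logging.getLogger(__name__)

#: First identifier used when minting local concepts (OMOP convention).
LOCAL_ID_START = 2_000_000_000

DOMAINS = frozenset(
    {
        "Condition",
        "Measurement",
        "Drug",
        "Procedure",
        "Episode",
        "Observation",
        "Spec Anatomic Site",
        "Meas Value",
        "Regimen",
        "Modifier",
    }
)


class Rel:
    """Relationship identifiers understood by the store."""

    MAPS_TO = "Maps to"
    IS_A = "Is a"
    HAS_FINDING_SITE = "Has finding site"
    HAS_ASSOC_MORPH = "Has associated morphology"
    HAS_HISTOLOGY = "Has Histology"
    HAS_TOPOGRAPHY = "Has Topography"
    HAS_CANCER_TYPE = "Has cancer type"
    HAS_REGIMEN_COMPONENT = "Has regimen component"
    ITEM_VALUE_MAPS_TO = "Item-value maps to"


RELATIONSHIP_IDS = frozenset(
    {
        Rel.MAPS_TO,
        Rel.IS_A,
        Rel.HAS_FINDING_SITE,
        Rel.HAS_ASSOC_MORPH,
        Rel.HAS_HISTOLOGY,
        Rel.HAS_TOPOGRAPHY,
        Rel.HAS_CANCER_TYPE,
        Rel.HAS_REGIMEN_COMPONENT,
        Rel.ITEM_VALUE_MAPS_TO,
    }
)

CONCEPT_COLUMNS = [
    "CONCEPT_ID",
    "CONCEPT_NAME",
    "DOMAIN_ID",
    "VOCABULARY_ID",
    "CONCEPT_CLASS_ID",
    "STANDARD_CONCEPT",
    "CONCEPT_CODE",
]
RELATIONSHIP_COLUMNS = ["CONCEPT_ID_1", "CONCEPT_ID_2", "RELATIONSHIP_ID"]
ANCESTOR_COLUMNS = [
    "ANCESTOR_CONCEPT_ID",
    "DESCENDANT_CONCEPT_ID",
    "MIN_LEVELS_OF_SEPARATION",
    "MAX_LEVELS_OF_SEPARATION",
]

CONCEPT_FILE = "CONCEPT.csv"
RELATIONSHIP_FILE = "CONCEPT_RELATIONSHIP.csv"
ANCESTOR_FILE = "CONCEPT_ANCESTOR.csv"


@dataclass
class Concept:
    """One vocabulary term.

    ``standard`` marks the designated canonical concept for its meaning;
    source codes reach standard concepts through ``Maps to``.
    """

    concept_id: int
    concept_name: str
    domain_id: str
    vocabulary_id: str
    concept_class_id: str
    concept_code: str
    standard: bool = False


@dataclass(frozen=True)
class ConceptRelationship:
    concept_id_1: int
    concept_id_2: int
    relationship_id: str


@dataclass(frozen=True)
class ConceptAncestor:
    ancestor_concept_id: int
    descendant_concept_id: int
    min_levels: int
    max_levels: int


class ConceptGraph:
    """Concepts plus typed relationships plus the derived ancestor closure."""

    def __init__(self, id_counter_start: int = LOCAL_ID_START):
        self._concepts: dict[int, Concept] = {}
        self._by_code: dict[tuple[str, str], int] = {}
        self._rels: list[ConceptRelationship] = []
        self._rel_set: set[ConceptRelationship] = set()
        self._out: dict[tuple[int, str], list[int]] = {}
        self._in: dict[tuple[int, str], list[int]] = {}
        # descendant -> {ancestor: (min, max)}; includes reflexive pairs
        self._closure: dict[int, dict[int, tuple[int, int]]] = {}
        self._desc_index: dict[int, set[int]] = {}
        self._closure_dirty = True
        self._id_counter = id_counter_start

    # -- basic access ------------------------------------------------------

    def __len__(self) -> int:
        return len(self._concepts)

    def __contains__(self, concept_id: int) -> bool:
        return concept_id in self._concepts

    def concepts(self) -> Iterator[Concept]:
        return iter(self._concepts.values())

    def concept(self, concept_id: int) -> Concept:
        try:
            return self._concepts[concept_id]
        except KeyError:
            raise VocabularyError(f"unknown concept_id {concept_id}") from None

    def get(self, concept_id: int) -> Concept | None:
        return self._concepts.get(concept_id)

    def by_code(self, vocabulary_id: str, concept_code: str) -> Concept | None:
        cid = self._by_code.get((vocabulary_id, concept_code))
        return None if cid is None else self._concepts[cid]

    @property
    def relationships(self) -> list[ConceptRelationship]:
        return list(self._rels)

    def n_relationships(self) -> int:
        return len(self._rels)

    # -- mutation ----------------------------------------------------------

    def add_concept(self, concept: Concept) -> Concept:
        if concept.concept_id in self._concepts:
            raise VocabularyError(f"duplicate concept_id {concept.concept_id}")
        if not concept.concept_code:
            raise VocabularyError(
                f"concept {concept.concept_id} has an empty concept_code"
            )
        key = (concept.vocabulary_id, concept.concept_code)
        if key in self._by_code:
            raise VocabularyError(
                f"duplicate (vocabulary, code) {key} for concept "
                f"{concept.concept_id}"
            )
        self._concepts[concept.concept_id] = concept
        self._by_code[key] = concept.concept_id
        self._closure_dirty = True
        return concept

    def add_relationship(
        self, concept_id_1: int, concept_id_2: int, relationship_id: str
    ) -> ConceptRelationship:
        if relationship_id not in RELATIONSHIP_IDS:
            raise VocabularyError(f"unknown relationship_id {relationship_id!r}")
        for cid in (concept_id_1, concept_id_2):
            if cid not in self._concepts:
                raise VocabularyError(
                    f"relationship endpoint {cid} is not a known concept"
                )
        if relationship_id == Rel.IS_A and concept_id_1 == concept_id_2:
            raise VocabularyError(f"'Is a' self-loop on concept {concept_id_1}")
        if relationship_id == Rel.MAPS_TO and not self._concepts[concept_id_2].standard:
            raise VocabularyError(
                f"'Maps to' target {concept_id_2} is not a standard concept"
            )
        rel = ConceptRelationship(concept_id_1, concept_id_2, relationship_id)
        if rel in self._rel_set:
            return rel
        self._rels.append(rel)
        self._rel_set.add(rel)
        self._out.setdefault((concept_id_1, relationship_id), []).append(concept_id_2)
        self._in.setdefault((concept_id_2, relationship_id), []).append(concept_id_1)
        if relationship_id == Rel.IS_A:
            self._closure_dirty = True
        return rel

    def has_relationship(
        self, concept_id_1: int, concept_id_2: int, relationship_id: str
    ) -> bool:
        return (
            ConceptRelationship(concept_id_1, concept_id_2, relationship_id)
            in self._rel_set
        )

    def set_standard(self, concept_id: int, standard: bool = True) -> None:
        self.concept(concept_id).standard = standard

    def new_concept_id(self) -> int:
        """Mint the next unused local concept id (deterministic counter)."""
        cid = self._id_counter
        while cid in self._concepts:
            cid += 1
        self._id_counter = cid + 1
        return cid

    # -- typed-edge queries ------------------------------------------------

    def targets(self, concept_id: int, relationship_id: str) -> list[int]:
        return list(self._out.get((concept_id, relationship_id), []))

    def sources(self, concept_id: int, relationship_id: str) -> list[int]:
        return list(self._in.get((concept_id, relationship_id), []))

    # -- hierarchy ---------------------------------------------------------

    def _ensure_closure(self) -> None:
        if self._closure_dirty:
            rebuild_ancestors(self)

    def ancestors_of(self, concept_id: int) -> set[int]:
        """All ancestors of ``concept_id`` through ``Is a``, including itself."""
        self.concept(concept_id)
        self._ensure_closure()
        return set(self._closure.get(concept_id, {concept_id: (0, 0)}))

    def descendants_of(self, concept_id: int) -> set[int]:
        """All descendants of ``concept_id`` through ``Is a``, including itself."""
        self.concept(concept_id)
        self._ensure_closure()
        return set(self._desc_index.get(concept_id, {concept_id}))

    def ancestor_levels(
        self, ancestor_id: int, descendant_id: int
    ) -> tuple[int, int] | None:
        self._ensure_closure()
        return self._closure.get(descendant_id, {}).get(ancestor_id)

    def ancestor_rows(self) -> list[ConceptAncestor]:
        self._ensure_closure()
        rows = [
            ConceptAncestor(anc, desc, mn, mx)
            for desc, ancs in self._closure.items()
            for anc, (mn, mx) in ancs.items()
        ]
        rows.sort(
            key=lambda r: (r.ancestor_concept_id, r.descendant_concept_id)
        )
        return rows

    def _set_closure(
        self, closure: dict[int, dict[int, tuple[int, int]]]
    ) -> None:
        self._closure = closure
        self._desc_index = {}
        for desc, ancs in closure.items():
            for anc in ancs:
                self._desc_index.setdefault(anc, set()).add(desc)
        self._closure_dirty = False


def rebuild_ancestors(graph: ConceptGraph) -> ConceptGraph:
    """Recompute the ancestor closure as the transitive closure of ``Is a``.

    min/max levels are the shortest and longest ``Is a`` path lengths;
    reflexive pairs are included with level 0.  Raises
    :class:`VocabularyError` if the ``Is a`` edges contain a cycle.
    """
    g = nx.DiGraph()
    g.add_nodes_from(c.concept_id for c in graph.concepts())
    for rel in graph.relationships:
        if rel.relationship_id == Rel.IS_A:
            g.add_edge(rel.concept_id_1, rel.concept_id_2)  # child -> parent
    if not nx.is_directed_acyclic_graph(g):
        cycle = [edge[0] for edge in nx.find_cycle(g)]
        raise VocabularyError(f"cycle in 'Is a' hierarchy: {cycle}")

    # children precede parents in topological order; walk parents first
    order = list(nx.topological_sort(g))
    closure: dict[int, dict[int, tuple[int, int]]] = {}
    for node in reversed(order):
        ancs: dict[int, tuple[int, int]] = {}
        for parent in g.successors(node):
            candidates = [(parent, 1, 1)] + [
                (a, mn + 1, mx + 1) for a, (mn, mx) in closure[parent].items()
            ]
            for a, mn, mx in candidates:
                if a == node:
                    continue
                cur = ancs.get(a)
                if cur is None:
                    ancs[a] = (mn, mx)
                else:
                    ancs[a] = (min(cur[0], mn), max(cur[1], mx))
        closure[node] = ancs
    # add reflexive rows last so parent walks above see only proper ancestors
    for node in closure:
        closure[node][node] = (0, 0)
    graph._set_closure(closure)
    return graph


def descendants_of(graph: ConceptGraph, concept_id: int) -> set[int]:
    """Module-level convenience wrapper for cohort expansion."""
    return graph.descendants_of(concept_id)


# -- file I/O ---------------------------------------------------------------


def _read_rows(path: Path, columns: list[str]) -> Iterator[tuple[int, list[str]]]:
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t", quoting=csv.QUOTE_NONE)
        try:
            header = next(reader)
        except StopIteration:
            raise VocabularyError(f"{path.name}: empty file, header expected")
        if [h.strip().upper() for h in header] != columns:
            raise VocabularyError(
                f"{path.name} line 1: expected header {columns}, got {header}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != len(columns):
                raise VocabularyError(
                    f"{path.name} line {lineno}: expected {len(columns)} "
                    f"fields, got {len(row)}"
                )
            yield lineno, row


def _parse_int(value: str, path: Path, lineno: int, what: str) -> int:
    try:
        return int(value)
    except ValueError:
        raise VocabularyError(
            f"{path.name} line {lineno}: {what} {value!r} is not an integer"
        ) from None


def load_vocab(directory: str | Path) -> ConceptGraph:
    """Load a vocabulary directory (CONCEPT, CONCEPT_RELATIONSHIP and,
    optionally, CONCEPT_ANCESTOR) into a validated :class:`ConceptGraph`.

    The ancestor closure is rebuilt from ``Is a`` edges when the
    CONCEPT_ANCESTOR file is absent.
    """
    directory = Path(directory)
    concept_path = directory / CONCEPT_FILE
    rel_path = directory / RELATIONSHIP_FILE
    if not concept_path.is_file():
        raise VocabularyError(f"missing {CONCEPT_FILE} in {directory}")
    if not rel_path.is_file():
        raise VocabularyError(f"missing {RELATIONSHIP_FILE} in {directory}")

    graph = ConceptGraph()
    for lineno, row in _read_rows(concept_path, CONCEPT_COLUMNS):
        cid = _parse_int(row[0], concept_path, lineno, "CONCEPT_ID")
        standard_flag = row[5].strip()
        if standard_flag not in ("", "S"):
            raise VocabularyError(
                f"{concept_path.name} line {lineno}: STANDARD_CONCEPT must be "
                f"'S' or empty, got {standard_flag!r}"
            )
        try:
            graph.add_concept(
                Concept(
                    concept_id=cid,
                    concept_name=row[1],
                    domain_id=row[2],
                    vocabulary_id=row[3],
                    concept_class_id=row[4],
                    concept_code=row[6],
                    standard=standard_flag == "S",
                )
            )
        except VocabularyError as exc:
            raise VocabularyError(
                f"{concept_path.name} line {lineno}: {exc}"
            ) from None

    for lineno, row in _read_rows(rel_path, RELATIONSHIP_COLUMNS):
        c1 = _parse_int(row[0], rel_path, lineno, "CONCEPT_ID_1")
        c2 = _parse_int(row[1], rel_path, lineno, "CONCEPT_ID_2")
        try:
            graph.add_relationship(c1, c2, row[2].strip())
        except VocabularyError as exc:
            raise VocabularyError(f"{rel_path.name} line {lineno}: {exc}") from None

    ancestor_path = directory / ANCESTOR_FILE
    if ancestor_path.is_file():
        closure: dict[int, dict[int, tuple[int, int]]] = {}
        for lineno, row in _read_rows(ancestor_path, ANCESTOR_COLUMNS):
            anc = _parse_int(row[0], ancestor_path, lineno, "ANCESTOR_CONCEPT_ID")
            desc = _parse_int(
                row[1], ancestor_path, lineno, "DESCENDANT_CONCEPT_ID"
            )
            mn = _parse_int(row[2], ancestor_path, lineno, "MIN_LEVELS")
            mx = _parse_int(row[3], ancestor_path, lineno, "MAX_LEVELS")
            for cid in (anc, desc):
                if cid not in graph:
                    raise VocabularyError(
                        f"{ancestor_path.name} line {lineno}: unknown "
                        f"concept {cid}"
                    )
            if mn > mx:
                raise VocabularyError(
                    f"{ancestor_path.name} line {lineno}: min_levels {mn} "
                    f"> max_levels {mx}"
                )
            closure.setdefault(desc, {})[anc] = (mn, mx)
        for c in graph.concepts():
            closure.setdefault(c.concept_id, {}).setdefault(c.concept_id, (0, 0))
        graph._set_closure(closure)
    else:
        rebuild_ancestors(graph)
    return graph


def write_vocab(graph: ConceptGraph, directory: str | Path) -> None:
    """Write the three vocabulary files in canonical (sorted) order."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    def _open(name: str):
        return (directory / name).open("w", newline="", encoding="utf-8")

    with _open(CONCEPT_FILE) as fh:
        w = csv.writer(fh, delimiter="\t", quoting=csv.QUOTE_NONE, lineterminator="\n")
        w.writerow(CONCEPT_COLUMNS)
        for c in sorted(graph.concepts(), key=lambda c: c.concept_id):
            w.writerow(
                [
                    c.concept_id,
                    c.concept_name,
                    c.domain_id,
                    c.vocabulary_id,
                    c.concept_class_id,
                    "S" if c.standard else "",
                    c.concept_code,
                ]
            )
    with _open(RELATIONSHIP_FILE) as fh:
        w = csv.writer(fh, delimiter="\t", quoting=csv.QUOTE_NONE, lineterminator="\n")
        w.writerow(RELATIONSHIP_COLUMNS)
        for r in sorted(
            graph.relationships,
            key=lambda r: (r.concept_id_1, r.relationship_id, r.concept_id_2),
        ):
            w.writerow([r.concept_id_1, r.concept_id_2, r.relationship_id])
    with _open(ANCESTOR_FILE) as fh:
        w = csv.writer(fh, delimiter="\t", quoting=csv.QUOTE_NONE, lineterminator="\n")
        w.writerow(ANCESTOR_COLUMNS)
        for a in graph.ancestor_rows():
            w.writerow(
                [
                    a.ancestor_concept_id,
                    a.descendant_concept_id,
                    a.min_levels,
                    a.max_levels,
                ]
            )


def validate_vocab(graph: ConceptGraph) -> list[str]:
    """Scan the graph for invariant violations; returns human-readable
    problem descriptions (empty list = clean)."""
    problems: list[str] = []
    for rel in graph.relationships:
        if rel.relationship_id == Rel.MAPS_TO:
            target = graph.get(rel.concept_id_2)
            if target is None or not target.standard:
                problems.append(
                    f"'Maps to' target {rel.concept_id_2} is not standard"
                )
    try:
        graph._ensure_closure()
    except VocabularyError as exc:
        problems.append(str(exc))
    return problems
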