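"""ICD-O-3 precoordination and the two-step SNOMED integration."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oncomop import (
    AttributePair,
    Concept,
    ConceptGraph,
    MappingError,
    MODE_EQUIVALENT,
    MODE_INSERTED,
    find_equivalent,
    insert_into_hierarchy,
    integrate,
    link_cancer_type,
    parse_icdo,
    precoordinate,
    rebuild_ancestors,
    resolve_attributes,
)
from oncomop import concepts as C
from oncomop.vocab_store import Rel


class TestParseIcdo:
    @pytest.mark.parametrize(
        "code,histology,behavior,topography",
        [
            ("8520/3-C50.9", "8520", "3", "C50.9"),
            ("8010/3-C50.9", "8010", "3", "C50.9"),
            ("  8140/2-C61  ", "8140", "2", "C61"),
        ],
    )
    def test_decomposes_valid_codes(self, code, histology, behavior, topography):
        icdo = parse_icdo(code)
        assert (icdo.histology, icdo.behavior, icdo.topography) == (
            histology,
            behavior,
            topography,
        )
        assert parse_icdo(icdo.combined_code) == icdo

    @pytest.mark.parametrize(
        "bad", ["8010/9-C50.9", "7000/3-C50.9", "8010-C50.9", "8010/3", "junk"]
    )
    def test_malformed_codes_quote_the_input(self, bad):
        with pytest.raises(MappingError, match=bad.replace("/", "/")):
            parse_icdo(bad)

    @given(
        histology=st.integers(8000, 9999),
        behavior=st.integers(0, 3),
        site=st.integers(0, 80),
        sub=st.one_of(st.none(), st.integers(0, 9)),
    )
    @settings(derandomize=True, max_examples=60)
    def test_round_trip_any_valid_code(self, histology, behavior, site, sub):
        topography = f"C{site:02d}" + ("" if sub is None else f".{sub}")
        code = f"{histology}/{behavior}-{topography}"
        icdo = parse_icdo(code)
        assert icdo.combined_code == code
        assert icdo.topography_prefix == f"C{site:02d}"


class TestPrecoordinate:
    def test_two_distinct_codes_two_concepts_four_attribute_edges(self, fig3_graph):
        before = fig3_graph.n_relationships()
        precoordinate(["8520/3-C50.9", "8010/3-C50.9"], fig3_graph)
        created = [
            c
            for c in fig3_graph.concepts()
            if c.vocabulary_id == "ICDO3" and "-" in c.concept_code
        ]
        assert {c.concept_code for c in created} == {"8520/3-C50.9", "8010/3-C50.9"}
        assert all(c.domain_id == "Condition" for c in created)
        assert fig3_graph.n_relationships() == before + 4

    def test_duplicates_collapse_to_one_concept(self, fig3_graph):
        precoordinate(["8520/3-C50.9", "8520/3-C50.9"], fig3_graph)
        created = [
            c for c in fig3_graph.concepts() if c.concept_code == "8520/3-C50.9"
        ]
        assert len(created) == 1

    def test_missing_component_names_the_code(self, fig3_graph):
        with pytest.raises(MappingError, match="8500/3"):
            precoordinate(["8500/3-C50.9"], fig3_graph)


class TestResolveAttributes:
    def test_topography_resolves_to_breast_structure(self, fig3_graph):
        pair = resolve_attributes("8010/3-C50.9", fig3_graph)
        assert pair.finding_site_concept_id == C.BREAST_STRUCTURE

    def test_histology_resolves_to_carcinoma_morphology(self, fig3_graph):
        pair = resolve_attributes("8010/3-C50.9", fig3_graph)
        assert pair.morphology_concept_id == C.CARCINOMA_MORPHOLOGY

    def test_missing_histology_mapping_names_the_axis(self, fig3_graph):
        fig3_graph.add_concept(
            Concept(999, "h", "Observation", "ICDO3", "ICDO Histology", "9999/3")
        )
        with pytest.raises(MappingError, match="histology"):
            resolve_attributes("9999/3-C50.9", fig3_graph)


class TestFindEquivalent:
    def test_lobular_pair_matches_infiltrating_lobular_carcinoma(self, fig3_graph):
        pair = AttributePair(C.LOBULAR_CARCINOMA_MORPHOLOGY, C.BREAST_STRUCTURE)
        assert (
            find_equivalent(pair, fig3_graph)
            == C.INFILTRATING_LOBULAR_CARCINOMA_OF_BREAST
        )

    def test_carcinoma_pair_has_no_exact_match(self, fig3_graph):
        # carcinoma of breast subsumes the intersection but its morphology
        # attribute is coarser, so it is not an exact equivalent
        pair = AttributePair(C.CARCINOMA_MORPHOLOGY, C.BREAST_STRUCTURE)
        assert find_equivalent(pair, fig3_graph) is None

    def test_empty_graph_gives_none(self):
        assert find_equivalent(AttributePair(1, 2), ConceptGraph()) is None


def _attribute_world(n_disorders, rng):
    """Random fixture: small morphology and site trees plus attributed
    disorders, for checking parent selection against a brute-force oracle."""
    g = ConceptGraph()
    n_morph, n_site = 6, 5
    for i in range(1, n_morph + 1):
        g.add_concept(Concept(100 + i, f"m{i}", "Observation", "SNOMED", "Morph Abnormality", f"m{i}", True))
        if i > 1:
            g.add_relationship(100 + i, 100 + rng.randint(1, i - 1), Rel.IS_A)
    for i in range(1, n_site + 1):
        g.add_concept(Concept(200 + i, f"s{i}", "Spec Anatomic Site", "SNOMED", "Body Structure", f"s{i}", True))
        if i > 1:
            g.add_relationship(200 + i, 200 + rng.randint(1, i - 1), Rel.IS_A)
    disorders = []
    for i in range(1, n_disorders + 1):
        morph = 100 + rng.randint(1, n_morph)
        site = 200 + rng.randint(1, n_site)
        g.add_concept(Concept(300 + i, f"d{i}", "Condition", "SNOMED", "Disorder", f"d{i}", True))
        g.add_relationship(300 + i, morph, Rel.HAS_ASSOC_MORPH)
        g.add_relationship(300 + i, site, Rel.HAS_FINDING_SITE)
        disorders.append((300 + i, morph, site))
    return g, disorders


def _oracle_minimal_parents(g, disorders, target_morph, target_site, exclude):
    """Brute force: enumerate subsuming disorders, prune any with another
    subsumer strictly below it (by attribute subsumption or hierarchy)."""

    def ancestors(cid):
        out, stack = {cid}, [cid]
        while stack:
            node = stack.pop()
            for parent in g.targets(node, Rel.IS_A):
                if parent not in out:
                    out.add(parent)
                    stack.append(parent)
        return out

    morph_anc, site_anc = ancestors(target_morph), ancestors(target_site)
    cands = [
        (d, m, s)
        for d, m, s in disorders
        if d != exclude and m in morph_anc and s in site_anc
    ]
    minimal = []
    for d, m, s in cands:
        dominated = any(
            (d2, m2, s2) != (d, m, s)
            and (
                (m in ancestors(m2) and s in ancestors(s2) and (m2, s2) != (m, s))
                or (d in ancestors(d2) and d2 != d)
            )
            for d2, m2, s2 in cands
        )
        if not dominated:
            minimal.append(d)
    return sorted(minimal)


class TestInsertIntoHierarchy:
    def test_worked_example_child_of_carcinoma_of_breast(self, fig3_graph):
        precoordinate(["8010/3-C50.9"], fig3_graph)
        cid = fig3_graph.by_code("ICDO3", "8010/3-C50.9").concept_id
        pair = resolve_attributes("8010/3-C50.9", fig3_graph)
        outcome = insert_into_hierarchy(cid, pair, fig3_graph)
        assert outcome.mode == MODE_INSERTED
        assert outcome.parent_concept_ids == (C.CARCINOMA_OF_BREAST,)
        assert fig3_graph.concept(cid).standard

    def test_most_specific_parent_wins_over_its_ancestor(self):
        # X (coarse attrs) ancestor of Y (exact attrs): parent must be Y only
        g = ConceptGraph()
        g.add_concept(Concept(101, "m-root", "Observation", "SNOMED", "Morph Abnormality", "mr", True))
        g.add_concept(Concept(102, "m-leaf", "Observation", "SNOMED", "Morph Abnormality", "ml", True))
        g.add_relationship(102, 101, Rel.IS_A)
        g.add_concept(Concept(201, "site", "Spec Anatomic Site", "SNOMED", "Body Structure", "s", True))
        for cid, morph in ((301, 101), (302, 102)):
            g.add_concept(Concept(cid, f"d{cid}", "Condition", "SNOMED", "Disorder", f"d{cid}", True))
            g.add_relationship(cid, morph, Rel.HAS_ASSOC_MORPH)
            g.add_relationship(cid, 201, Rel.HAS_FINDING_SITE)
        g.add_relationship(302, 301, Rel.IS_A)
        g.add_concept(Concept(400, "new", "Condition", "ICDO3", "ICDO Condition", "8000/3-C00.0"))
        g.add_concept(Concept(103, "m-child", "Observation", "SNOMED", "Morph Abnormality", "mc", True))
        g.add_relationship(103, 102, Rel.IS_A)
        outcome = insert_into_hierarchy(400, AttributePair(103, 201), g)
        assert outcome.parent_concept_ids == (302,)

    def test_no_subsumer_falls_back_to_configured_root(self, caplog):
        g = ConceptGraph()
        g.add_concept(Concept(1, "root", "Condition", "SNOMED", "Disorder", "root", True))
        g.add_concept(Concept(101, "m", "Observation", "SNOMED", "Morph Abnormality", "m", True))
        g.add_concept(Concept(201, "s", "Spec Anatomic Site", "SNOMED", "Body Structure", "s", True))
        g.add_concept(Concept(400, "new", "Condition", "ICDO3", "ICDO Condition", "8000/3-C00.0"))
        with caplog.at_level("WARNING"):
            outcome = insert_into_hierarchy(400, AttributePair(101, 201), g, fallback_root=1)
        assert outcome.parent_concept_ids == (1,)
        assert any("no subsuming disorder" in r.message for r in caplog.records)

    @pytest.mark.parametrize("seed", range(8))
    def test_parent_selection_agrees_with_brute_force_oracle(self, seed):
        rng = random.Random(seed)
        g, disorders = _attribute_world(rng.randint(3, 50), rng)
        target_morph = 100 + rng.randint(1, 6)
        target_site = 200 + rng.randint(1, 5)
        g.add_concept(Concept(999, "new", "Condition", "ICDO3", "ICDO Condition", "8000/3-C00.0"))
        expected = _oracle_minimal_parents(g, disorders, target_morph, target_site, 999)
        outcome = insert_into_hierarchy(
            999, AttributePair(target_morph, target_site), g, fallback_root=301
        )
        if expected:
            assert list(outcome.parent_concept_ids) == expected
        else:
            assert outcome.parent_concept_ids == (301,)


class TestIntegrate:
    def test_equivalent_worked_example(self, integrated_graph):
        cid = integrated_graph.by_code("ICDO3", "8520/3-C50.9").concept_id
        outcome = integrate(cid, integrated_graph)
        assert outcome.mode == MODE_EQUIVALENT
        assert outcome.standard_concept_id == C.INFILTRATING_LOBULAR_CARCINOMA_OF_BREAST
        assert not integrated_graph.concept(cid).standard

    def test_inserted_worked_example(self, integrated_graph):
        cid = integrated_graph.by_code("ICDO3", "8010/3-C50.9").concept_id
        outcome = integrate(cid, integrated_graph)
        assert outcome.mode == MODE_INSERTED
        assert outcome.standard_concept_id == cid
        assert outcome.parent_concept_ids == (C.CARCINOMA_OF_BREAST,)

    def test_exactly_one_of_mapped_or_standard_with_parent(self, integrated_graph):
        for code in ("8520/3-C50.9", "8010/3-C50.9"):
            c = integrated_graph.by_code("ICDO3", code)
            mapped = bool(integrated_graph.targets(c.concept_id, Rel.MAPS_TO))
            inserted = c.standard and bool(
                integrated_graph.targets(c.concept_id, Rel.IS_A)
            )
            assert mapped != inserted  # never both, never neither

    def test_idempotent(self, fixture_graph):
        precoordinate(["8520/3-C50.9", "8010/3-C50.9"], fixture_graph)
        ids = sorted(
            c.concept_id
            for c in fixture_graph.concepts()
            if "-" in c.concept_code and c.vocabulary_id == "ICDO3"
        )
        first = [integrate(i, fixture_graph) for i in ids]
        rels_after_first = sorted(
            (r.concept_id_1, r.relationship_id, r.concept_id_2)
            for r in fixture_graph.relationships
        )
        second = [integrate(i, fixture_graph) for i in ids]
        assert first == second
        assert rels_after_first == sorted(
            (r.concept_id_1, r.relationship_id, r.concept_id_2)
            for r in fixture_graph.relationships
        )

    def test_hierarchy_preservation_after_insertion(self, fixture_graph):
        pre_pairs = {
            (r.ancestor_concept_id, r.descendant_concept_id)
            for r in fixture_graph.ancestor_rows()
        }
        precoordinate(["8010/3-C50.9"], fixture_graph)
        cid = fixture_graph.by_code("ICDO3", "8010/3-C50.9").concept_id
        integrate(cid, fixture_graph)
        post_pairs = {
            (r.ancestor_concept_id, r.descendant_concept_id)
            for r in fixture_graph.ancestor_rows()
        }
        assert pre_pairs <= post_pairs
        assert cid in fixture_graph.descendants_of(C.CARCINOMA_OF_BREAST)
        assert (
            C.INFILTRATING_LOBULAR_CARCINOMA_OF_BREAST
            in fixture_graph.descendants_of(C.CARCINOMA_OF_BREAST)
        )


class TestLinkCancerType:
    def test_c50_rule_links_breast_type(self, integrated_graph):
        cid = integrated_graph.by_code("ICDO3", "8010/3-C50.9").concept_id
        link_cancer_type(cid, integrated_graph, {"C50": C.CANCER_TYPE_BREAST})
        assert integrated_graph.targets(cid, Rel.HAS_CANCER_TYPE) == [
            C.CANCER_TYPE_BREAST
        ]

    def test_uncovered_prefix_warns_without_edge(self, integrated_graph, caplog):
        cid = integrated_graph.by_code("ICDO3", "8010/3-C50.9").concept_id
        with caplog.at_level("WARNING"):
            link_cancer_type(cid, integrated_graph, {"C61": C.CANCER_TYPE_BREAST})
        assert integrated_graph.targets(cid, Rel.HAS_CANCER_TYPE) == []
        assert any("C50" in r.message for r in caplog.records)

    def test_empty_rules_leave_graph_unchanged(self, integrated_graph):
        cid = integrated_graph.by_code("ICDO3", "8010/3-C50.9").concept_id
        n = integrated_graph.n_relationships()
        link_cancer_type(cid, integrated_graph, {})
        assert integrated_graph.n_relationships() == n
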