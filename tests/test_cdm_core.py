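"""CDM store: modifier linkage, episode nesting, death reconciliation, I/O."""

import random
from datetime import date

import pytest

from oncomop import (
    CdmStore,
    ConditionOccurrence,
    DeathRecord,
    DrugExposure,
    IntegrityError,
    ModifierMeasurement,
    Person,
    SOURCE_EHR,
    SOURCE_REGISTRY,
    merge_vital_status,
    read_cdm,
    write_cdm,
)
from oncomop import concepts as C

from conftest import day


@pytest.fixture
def store_with_condition(store):
    store.add_condition(
        ConditionOccurrence(10, 1, C.CARCINOMA_OF_BREAST, day(0), "8010/3-C50.9")
    )
    return store


class TestAttachModifier:
    def test_categorical_modifier_retrievable_via_condition(self, store_with_condition):
        s = store_with_condition
        s.attach_modifier(
            ModifierMeasurement(
                1, 1, C.METASTASIS_STATUS, value_concept_id=C.METASTATIC,
                modifier_of_event_id=10,
                modifier_of_field_concept_id=C.FIELD_CONDITION_OCCURRENCE,
            )
        )
        mods = s.modifiers_of(10)
        assert [m.value_concept_id for m in mods] == [C.METASTATIC]

    def test_numeric_modifier_stored_with_value_number(self, store_with_condition):
        m = store_with_condition.attach_modifier(
            ModifierMeasurement(
                2, 1, C.TUMOR_SIZE, value_number=23.0, units="mm",
                modifier_of_event_id=10,
                modifier_of_field_concept_id=C.FIELD_CONDITION_OCCURRENCE,
            )
        )
        assert m.value_number == 23.0 and m.value_concept_id is None

    def test_cross_person_linkage_rejected(self, store_with_condition):
        with pytest.raises(IntegrityError, match="person"):
            store_with_condition.attach_modifier(
                ModifierMeasurement(
                    3, 2, C.METASTASIS_STATUS, value_concept_id=C.METASTATIC,
                    modifier_of_event_id=10,
                    modifier_of_field_concept_id=C.FIELD_CONDITION_OCCURRENCE,
                )
            )

    def test_dangling_target_rejected(self, store):
        with pytest.raises(IntegrityError, match="999"):
            store.attach_modifier(
                ModifierMeasurement(
                    4, 1, C.METASTASIS_STATUS, value_concept_id=C.METASTATIC,
                    modifier_of_event_id=999,
                    modifier_of_field_concept_id=C.FIELD_CONDITION_OCCURRENCE,
                )
            )

    def test_exactly_one_value_required(self, store_with_condition):
        with pytest.raises(IntegrityError, match="exactly one"):
            store_with_condition.attach_modifier(
                ModifierMeasurement(
                    5, 1, C.TUMOR_SIZE, value_concept_id=C.METASTATIC,
                    value_number=1.0, modifier_of_event_id=10,
                    modifier_of_field_concept_id=C.FIELD_CONDITION_OCCURRENCE,
                )
            )


class TestEpisodes:
    def test_regimen_with_three_nested_cycles(self, store):
        reg = store.create_episode(
            person_id=1, episode_concept_id=C.TREATMENT_REGIMEN,
            episode_object_concept_id=C.REGIMEN_PACLITAXEL_BEVACIZUMAB,
            start_date=day(0), end_date=day(62),
        )
        for i in range(3):
            cycle = store.create_episode(
                person_id=1, episode_concept_id=C.TREATMENT_CYCLE,
                episode_object_concept_id=C.REGIMEN_PACLITAXEL_BEVACIZUMAB,
                start_date=day(21 * i), end_date=day(21 * i + 20),
                episode_parent_id=reg.episode_id, episode_number=i + 1,
            )
            assert cycle.episode_parent_id == reg.episode_id
        assert store.validate() == []

    def test_cycle_outside_regimen_interval_rejected(self, store):
        reg = store.create_episode(
            person_id=1, episode_concept_id=C.TREATMENT_REGIMEN,
            episode_object_concept_id=C.REGIMEN_PACLITAXEL_BEVACIZUMAB,
            start_date=day(0), end_date=day(20),
        )
        with pytest.raises(IntegrityError, match="not contained"):
            store.create_episode(
                person_id=1, episode_concept_id=C.TREATMENT_CYCLE,
                episode_object_concept_id=C.REGIMEN_PACLITAXEL_BEVACIZUMAB,
                start_date=day(30), end_date=day(50),
                episode_parent_id=reg.episode_id, episode_number=1,
            )

    def test_drug_exposure_links_inside_cycle_window(self, store):
        store.add_drug_exposure(
            DrugExposure(100, 1, C.PACLITAXEL, day(5), day(5))
        )
        cycle = store.create_episode(
            person_id=1, episode_concept_id=C.TREATMENT_CYCLE,
            episode_object_concept_id=C.REGIMEN_PACLITAXEL_BEVACIZUMAB,
            start_date=day(0), end_date=day(20), episode_number=1,
        )
        link = store.link_event(cycle.episode_id, 100, C.FIELD_DRUG_EXPOSURE)
        assert link in store.episode_events

    def test_event_outside_episode_rejected(self, store):
        store.add_drug_exposure(
            DrugExposure(101, 1, C.PACLITAXEL, day(30), day(30))
        )
        cycle = store.create_episode(
            person_id=1, episode_concept_id=C.TREATMENT_CYCLE,
            episode_object_concept_id=C.REGIMEN_PACLITAXEL_BEVACIZUMAB,
            start_date=day(0), end_date=day(20), episode_number=1,
        )
        with pytest.raises(IntegrityError, match="outside"):
            store.link_event(cycle.episode_id, 101, C.FIELD_DRUG_EXPOSURE)


class TestMergeVitalStatus:
    def test_registry_only_death_doubles_singleton_count(self):
        ehr = [DeathRecord(1, day(0), SOURCE_EHR)]
        registry = [
            DeathRecord(1, day(0), SOURCE_REGISTRY),
            DeathRecord(2, day(5), SOURCE_REGISTRY),
        ]
        merged, report = merge_vital_status(ehr, registry)
        assert report.additional_deaths == 1
        assert report.percent_increase == 100.0
        assert {d.person_id for d in merged} == {1, 2}

    def test_brute_force_formula_on_random_lists(self):
        # oracle: percent increase is 100 x |registry-only persons| / |EHR persons|
        rng = random.Random(0)
        for _ in range(25):
            ehr_persons = set(rng.sample(range(1, 500), rng.randint(1, 60)))
            reg_persons = set(rng.sample(range(1, 500), rng.randint(0, 60)))
            ehr = [DeathRecord(p, day(p % 30), SOURCE_EHR) for p in ehr_persons]
            registry = [DeathRecord(p, day(p % 30), SOURCE_REGISTRY) for p in reg_persons]
            _, report = merge_vital_status(ehr, registry)
            expected = 100.0 * len(reg_persons - ehr_persons) / len(ehr_persons)
            assert report.percent_increase == pytest.approx(expected)

    def test_published_arithmetic_75_additional_is_26_percent(self):
        # 288 EHR deaths + 75 registry-only deaths is a ~26% increase
        ehr = [DeathRecord(p, day(0), SOURCE_EHR) for p in range(1, 289)]
        registry = [DeathRecord(p, day(1), SOURCE_REGISTRY) for p in range(289, 364)]
        _, report = merge_vital_status(ehr, registry)
        assert report.additional_deaths == 75
        assert report.percent_increase == pytest.approx(26.04, abs=0.01)

    def test_empty_inputs_give_zero(self):
        merged, report = merge_vital_status([], [])
        assert merged == [] and report.additional_deaths == 0
        assert report.percent_increase == 0.0

    def test_conflicting_dates_keep_earlier_and_flag(self):
        ehr = [DeathRecord(1, day(10), SOURCE_EHR)]
        registry = [DeathRecord(1, day(3), SOURCE_REGISTRY)]
        merged, report = merge_vital_status(ehr, registry)
        assert merged[0].death_date == day(3)
        assert report.conflicting_persons == [1]

    def test_union_commutative_and_idempotent(self):
        a = [DeathRecord(1, day(0), SOURCE_EHR), DeathRecord(2, day(1), SOURCE_EHR)]
        b = [DeathRecord(2, day(1), SOURCE_REGISTRY), DeathRecord(3, day(2), SOURCE_REGISTRY)]
        m1, _ = merge_vital_status(a, b)
        m2, _ = merge_vital_status(b, a)
        assert {(d.person_id, d.death_date) for d in m1} == {
            (d.person_id, d.death_date) for d in m2
        }
        m3, _ = merge_vital_status(m1, [])
        assert {(d.person_id, d.death_date) for d in m3} == {
            (d.person_id, d.death_date) for d in m1
        }


class TestRoundTrip:
    def test_write_read_preserves_all_tables(self, tmp_path, store_with_condition):
        s = store_with_condition
        s.attach_modifier(
            ModifierMeasurement(
                1, 1, C.TUMOR_SIZE, value_number=23.0, units="mm",
                modifier_of_event_id=10,
                modifier_of_field_concept_id=C.FIELD_CONDITION_OCCURRENCE,
            )
        )
        s.add_drug_exposure(DrugExposure(100, 1, C.PACLITAXEL, day(0), day(0), 1.0))
        reg = s.create_episode(
            person_id=1, episode_concept_id=C.TREATMENT_REGIMEN,
            episode_object_concept_id=C.REGIMEN_PACLITAXEL_BEVACIZUMAB,
            start_date=day(0), end_date=day(20), episode_number=1,
        )
        s.link_event(reg.episode_id, 100, C.FIELD_DRUG_EXPOSURE)
        s.deaths.append(DeathRecord(2, day(100), SOURCE_EHR))
        write_cdm(s, tmp_path)
        loaded = read_cdm(tmp_path)
        assert loaded.persons.keys() == s.persons.keys()
        assert loaded.conditions[10].source_code == "8010/3-C50.9"
        assert loaded.measurements[1].value_number == 23.0
        assert loaded.measurements[1].units == "mm"
        assert loaded.episodes[reg.episode_id].episode_number == 1
        assert loaded.episode_events == s.episode_events
        assert loaded.deaths == s.deaths
        assert loaded.validate() == []
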