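"""Seeded generators for every input the toolkit consumes.

Two generators live here:

* :func:`make_fig3_vocab` / :func:`make_fixture_vocab` build the breast-cancer
  vocabulary subtree used by the worked integration examples — the published
  SNOMED identifiers (breast structure 76752008, carcinoma morphology
  68453008, carcinoma of breast 254838004, infiltrating lobular carcinoma of
  breast 278054005) plus the ICD-O-3 component concepts, episode concepts,
  ingredients and regimen concepts.  Output is deterministic and
  byte-identical across runs.

* :func:`simulate_patients` plants known regimen histories, diagnoses,
  registry abstracts and death records for a configurable number of
  synthetic persons, and returns the ground truth needed to score detection
  and ETL recovery.

In the Figure-3 subtree the ``carcinoma of breast`` disorder carries the
coarser *malignant epithelial neoplasm* morphology rather than *carcinoma*
itself; this realizes the published outcome that ``8010/3-C50.9`` finds no
exact attribute match yet is inserted as a child of carcinoma of breast.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path

import numpy as np

from . import concepts as C
from .cdm_core import (
    CdmStore,
    DeathRecord,
    DrugExposure,
    Person,
    SOURCE_EHR,
    write_cdm,
)
from .naaccr_etl import (
    ITEM_BEHAVIOR,
    ITEM_DATE_OF_DIAGNOSIS,
    ITEM_DATE_OF_LAST_CONTACT,
    ITEM_HISTOLOGY,
    ITEM_PRIMARY_SITE,
    ITEM_VITAL_STATUS,
    ItemMappingRule,
    KIND_MODIFIER_CATEGORICAL,
    KIND_MODIFIER_NUMERIC,
    KIND_VITAL_STATUS,
    RegistryRecord,
    VITAL_ALIVE,
    VITAL_DEAD,
    write_mapping_rules,
    write_registry_records,
)
from .regimen_detection import RegimenDefinition, write_regimen_definitions
from .vocab_store import Concept, ConceptGraph, Rel, rebuild_ancestors, write_vocab

ITEM_METASTASIS = "3000"  # synthetic modifier item: metastatic status
ITEM_ER_STATUS = "2880"  # estrogen receptor status
ITEM_TUMOR_SIZE = "2800"  # tumor size, mm

#: (combined code, site item value, histology, behavior) for the two
#: breast-cancer worked examples; the first maps to SNOMED, the second is
#: inserted into the hierarchy.
DIAGNOSIS_CATALOG = (
    ("8520/3-C50.9", "C509", "8520", "3"),
    ("8010/3-C50.9", "C509", "8010", "3"),
)


def _c(cid, name, domain, vocab, cls, code, standard=False) -> Concept:
    return Concept(cid, name, domain, vocab, cls, code, standard)


def _fig3_concepts() -> list[Concept]:
    return [
        _c(C.BREAST_STRUCTURE, "Breast structure", "Spec Anatomic Site", "SNOMED",
           "Body Structure", "76752008", True),
        _c(C.MALIGNANT_EPITHELIAL_NEOPLASM_MORPHOLOGY,
           "Malignant epithelial neoplasm (morphologic abnormality)",
           "Observation", "SNOMED", "Morph Abnormality", "OMOP-MEN", True),
        _c(C.CARCINOMA_MORPHOLOGY, "Carcinoma (morphologic abnormality)",
           "Observation", "SNOMED", "Morph Abnormality", "68453008", True),
        _c(C.LOBULAR_CARCINOMA_MORPHOLOGY,
           "Lobular carcinoma (morphologic abnormality)",
           "Observation", "SNOMED", "Morph Abnormality", "OMOP-LCM", True),
        _c(C.NEOPLASTIC_DISEASE, "Neoplastic disease", "Condition", "SNOMED",
           "Disorder", "OMOP-ND", True),
        _c(C.CARCINOMA_OF_BREAST, "Carcinoma of breast", "Condition", "SNOMED",
           "Disorder", "254838004", True),
        _c(C.INFILTRATING_LOBULAR_CARCINOMA_OF_BREAST,
           "Infiltrating lobular carcinoma of breast", "Condition", "SNOMED",
           "Disorder", "278054005", True),
        _c(C.ICDO_HISTOLOGY_8520_3, "Lobular carcinoma, NOS", "Observation",
           "ICDO3", "ICDO Histology", "8520/3"),
        _c(C.ICDO_HISTOLOGY_8010_3, "Carcinoma, NOS", "Observation",
           "ICDO3", "ICDO Histology", "8010/3"),
        _c(C.ICDO_TOPOGRAPHY_C50_9, "Breast, NOS", "Spec Anatomic Site",
           "ICDO3", "ICDO Topography", "C50.9"),
        _c(C.CANCER_TYPE_BREAST, "Cancer type: breast", "Condition",
           "OMOP Extension", "Cancer Type", "OMOP-CT-BREAST", True),
        _c(C.DISEASE_FIRST_OCCURRENCE, "Disease First Occurrence", "Episode",
           "OMOP Extension", "Episode Type", "OMOP-EP-DFO", True),
        _c(C.TREATMENT_REGIMEN, "Treatment Regimen", "Episode",
           "OMOP Extension", "Episode Type", "OMOP-EP-REG", True),
        _c(C.TREATMENT_CYCLE, "Treatment Cycle", "Episode",
           "OMOP Extension", "Episode Type", "OMOP-EP-CYC", True),
    ]


_FIG3_RELATIONSHIPS = [
    # morphology hierarchy
    (C.CARCINOMA_MORPHOLOGY, C.MALIGNANT_EPITHELIAL_NEOPLASM_MORPHOLOGY, Rel.IS_A),
    (C.LOBULAR_CARCINOMA_MORPHOLOGY, C.CARCINOMA_MORPHOLOGY, Rel.IS_A),
    # disorder hierarchy with defining attributes
    (C.CARCINOMA_OF_BREAST, C.NEOPLASTIC_DISEASE, Rel.IS_A),
    (C.CARCINOMA_OF_BREAST, C.MALIGNANT_EPITHELIAL_NEOPLASM_MORPHOLOGY,
     Rel.HAS_ASSOC_MORPH),
    (C.CARCINOMA_OF_BREAST, C.BREAST_STRUCTURE, Rel.HAS_FINDING_SITE),
    (C.INFILTRATING_LOBULAR_CARCINOMA_OF_BREAST, C.CARCINOMA_OF_BREAST, Rel.IS_A),
    (C.INFILTRATING_LOBULAR_CARCINOMA_OF_BREAST, C.LOBULAR_CARCINOMA_MORPHOLOGY,
     Rel.HAS_ASSOC_MORPH),
    (C.INFILTRATING_LOBULAR_CARCINOMA_OF_BREAST, C.BREAST_STRUCTURE,
     Rel.HAS_FINDING_SITE),
    # ICD-O component equivalences (step 1 of integration)
    (C.ICDO_HISTOLOGY_8520_3, C.LOBULAR_CARCINOMA_MORPHOLOGY, Rel.MAPS_TO),
    (C.ICDO_HISTOLOGY_8010_3, C.CARCINOMA_MORPHOLOGY, Rel.MAPS_TO),
    (C.ICDO_TOPOGRAPHY_C50_9, C.BREAST_STRUCTURE, Rel.MAPS_TO),
]


def make_fig3_vocab(out_dir: str | Path | None = None) -> ConceptGraph:
    """The 14-concept breast-cancer subtree behind the worked examples."""
    graph = ConceptGraph()
    for concept in _fig3_concepts():
        graph.add_concept(concept)
    for c1, c2, rel in _FIG3_RELATIONSHIPS:
        graph.add_relationship(c1, c2, rel)
    rebuild_ancestors(graph)
    if out_dir is not None:
        write_vocab(graph, out_dir)
    return graph


def _treatment_concepts() -> list[Concept]:
    return [
        _c(C.DISEASE_PROGRESSION, "Disease Progression", "Episode",
           "OMOP Extension", "Episode Type", "OMOP-EP-PROG", True),
        _c(C.ANTINEOPLASTIC_AGENT, "Antineoplastic agent", "Drug", "RxNorm",
           "Drug Class", "OMOP-ANTINEO", True),
        _c(C.PACLITAXEL, "paclitaxel", "Drug", "RxNorm", "Ingredient", "56946", True),
        _c(C.BEVACIZUMAB, "bevacizumab", "Drug", "RxNorm", "Ingredient", "337521", True),
        _c(C.GEMCITABINE, "gemcitabine", "Drug", "RxNorm", "Ingredient", "12574", True),
        _c(C.CISPLATIN, "cisplatin", "Drug", "RxNorm", "Ingredient", "2555", True),
        _c(C.DEXAMETHASONE, "dexamethasone", "Drug", "RxNorm", "Ingredient", "3264", True),
        _c(C.ONDANSETRON, "ondansetron", "Drug", "RxNorm", "Ingredient", "26225", True),
        _c(C.PACLITAXEL_INJECTION, "paclitaxel 100 MG Injection", "Drug",
           "RxNorm", "Clinical Drug", "OMOP-PAC-INJ"),
        _c(C.REGIMEN_PACLITAXEL_BEVACIZUMAB, "Paclitaxel and Bevacizumab",
           "Regimen", "HemOnc", "Regimen", "OMOP-REG-PB", True),
        _c(C.REGIMEN_GEMCITABINE_CISPLATIN, "Gemcitabine and Cisplatin",
           "Regimen", "HemOnc", "Regimen", "OMOP-REG-GC", True),
        _c(C.REGIMEN_GEMCITABINE_MONO, "Gemcitabine monotherapy",
           "Regimen", "HemOnc", "Regimen", "OMOP-REG-GEM", True),
        _c(C.METASTASIS_STATUS, "Metastasis status", "Measurement",
           "OMOP Extension", "Modifier", "OMOP-MOD-METS", True),
        _c(C.METASTATIC, "Metastatic", "Meas Value", "OMOP Extension",
           "Modifier Value", "OMOP-VAL-MET", True),
        _c(C.NOT_METASTATIC, "Not metastatic", "Meas Value", "OMOP Extension",
           "Modifier Value", "OMOP-VAL-NOMET", True),
        _c(C.ER_STATUS, "Estrogen receptor status", "Measurement",
           "OMOP Extension", "Modifier", "OMOP-MOD-ER", True),
        _c(C.ER_POSITIVE, "Estrogen receptor positive", "Meas Value",
           "OMOP Extension", "Modifier Value", "OMOP-VAL-ERPOS", True),
        _c(C.ER_NEGATIVE, "Estrogen receptor negative", "Meas Value",
           "OMOP Extension", "Modifier Value", "OMOP-VAL-ERNEG", True),
        _c(C.TUMOR_SIZE, "Tumor size", "Measurement", "OMOP Extension",
           "Modifier", "OMOP-MOD-SIZE", True),
        _c(C.FIELD_CONDITION_OCCURRENCE, "condition_occurrence table",
           "Observation", "OMOP Extension", "Field", "OMOP-FLD-CO", True),
        _c(C.FIELD_DRUG_EXPOSURE, "drug_exposure table", "Observation",
           "OMOP Extension", "Field", "OMOP-FLD-DE", True),
        _c(C.FIELD_EPISODE, "episode table", "Observation", "OMOP Extension",
           "Field", "OMOP-FLD-EP", True),
    ]


_TREATMENT_RELATIONSHIPS = [
    (C.PACLITAXEL, C.ANTINEOPLASTIC_AGENT, Rel.IS_A),
    (C.BEVACIZUMAB, C.ANTINEOPLASTIC_AGENT, Rel.IS_A),
    (C.GEMCITABINE, C.ANTINEOPLASTIC_AGENT, Rel.IS_A),
    (C.CISPLATIN, C.ANTINEOPLASTIC_AGENT, Rel.IS_A),
    (C.PACLITAXEL_INJECTION, C.PACLITAXEL, Rel.MAPS_TO),
    (C.REGIMEN_PACLITAXEL_BEVACIZUMAB, C.PACLITAXEL, Rel.HAS_REGIMEN_COMPONENT),
    (C.REGIMEN_PACLITAXEL_BEVACIZUMAB, C.BEVACIZUMAB, Rel.HAS_REGIMEN_COMPONENT),
    (C.REGIMEN_GEMCITABINE_CISPLATIN, C.GEMCITABINE, Rel.HAS_REGIMEN_COMPONENT),
    (C.REGIMEN_GEMCITABINE_CISPLATIN, C.CISPLATIN, Rel.HAS_REGIMEN_COMPONENT),
    (C.REGIMEN_GEMCITABINE_MONO, C.GEMCITABINE, Rel.HAS_REGIMEN_COMPONENT),
]


def make_fixture_vocab(out_dir: str | Path | None = None) -> ConceptGraph:
    """Full fixture vocabulary: the Figure-3 subtree plus episode, drug,
    regimen, modifier and table-field concepts."""
    graph = make_fig3_vocab()
    for concept in _treatment_concepts():
        graph.add_concept(concept)
    for c1, c2, rel in _TREATMENT_RELATIONSHIPS:
        graph.add_relationship(c1, c2, rel)
    rebuild_ancestors(graph)
    if out_dir is not None:
        write_vocab(graph, out_dir)
    return graph


def default_regimen_definitions() -> list[RegimenDefinition]:
    """HemOnc-style definitions matching the fixture regimen concepts."""
    return [
        RegimenDefinition(
            C.REGIMEN_PACLITAXEL_BEVACIZUMAB,
            "Paclitaxel and Bevacizumab",
            frozenset({C.PACLITAXEL, C.BEVACIZUMAB}),
            21,
        ),
        RegimenDefinition(
            C.REGIMEN_GEMCITABINE_CISPLATIN,
            "Gemcitabine and Cisplatin",
            frozenset({C.GEMCITABINE, C.CISPLATIN}),
            21,
        ),
        RegimenDefinition(
            C.REGIMEN_GEMCITABINE_MONO,
            "Gemcitabine monotherapy",
            frozenset({C.GEMCITABINE}),
            28,
        ),
    ]


def default_mapping_rules() -> list[ItemMappingRule]:
    """Item-mapping rules for the synthetic registry dialect."""
    return [
        ItemMappingRule(
            ITEM_METASTASIS,
            KIND_MODIFIER_CATEGORICAL,
            measurement_concept_id=C.METASTASIS_STATUS,
            value_map={"1": C.METASTATIC, "0": C.NOT_METASTATIC},
        ),
        ItemMappingRule(
            ITEM_ER_STATUS,
            KIND_MODIFIER_CATEGORICAL,
            measurement_concept_id=C.ER_STATUS,
            value_map={"P": C.ER_POSITIVE, "N": C.ER_NEGATIVE},
        ),
        ItemMappingRule(
            ITEM_TUMOR_SIZE,
            KIND_MODIFIER_NUMERIC,
            measurement_concept_id=C.TUMOR_SIZE,
            units="mm",
        ),
        ItemMappingRule(
            ITEM_VITAL_STATUS,
            KIND_VITAL_STATUS,
            value_map={"0": VITAL_DEAD, "1": VITAL_ALIVE},
        ),
    ]


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    The defaults describe a noise-free cohort of 200 persons; timing jitter
    and co-medication are switched on explicitly when robustness is under
    study.
    """

    n_persons: int = 200
    seed: int = 7
    #: regimen concept -> planted sampling weight
    regimen_frequencies: dict = field(
        default_factory=lambda: {
            C.REGIMEN_PACLITAXEL_BEVACIZUMAB: 0.45,
            C.REGIMEN_GEMCITABINE_CISPLATIN: 0.35,
            C.REGIMEN_GEMCITABINE_MONO: 0.20,
        }
    )
    second_regimen_probability: float = 0.3
    min_cycles: int = 2
    max_cycles: int = 6
    cycle_jitter_days: int = 0
    comedication_rate: float = 0.0  # co-med exposures per planted exposure
    fraction_metastatic: float = 0.6
    registry_coverage: float = 0.9
    ehr_death_rate: float = 0.25
    registry_extra_death_rate: float = 0.08

    def validate(self) -> None:
        if self.n_persons < 1:
            raise ValueError("n_persons must be >= 1")
        for name in (
            "second_regimen_probability",
            "comedication_rate",
            "fraction_metastatic",
            "registry_coverage",
            "ehr_death_rate",
            "registry_extra_death_rate",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if not 1 <= self.min_cycles <= self.max_cycles:
            raise ValueError("need 1 <= min_cycles <= max_cycles")
        if self.cycle_jitter_days < 0:
            raise ValueError("cycle_jitter_days must be >= 0")
        total = sum(self.regimen_frequencies.values())
        if not self.regimen_frequencies or total <= 0:
            raise ValueError("regimen_frequencies must have positive total weight")


@dataclass
class PlantedRegimen:
    person_id: int
    regimen_concept_id: int
    line_number: int
    cycle_starts: list[date]


@dataclass
class SimulationResult:
    store: CdmStore
    registry_records: list[RegistryRecord]
    planted_regimens: list[PlantedRegimen]
    diagnoses: dict  # person_id -> combined ICD-O code
    diagnosis_dates: dict  # person_id -> date
    metastatic_persons: set
    ehr_death_persons: set
    registry_only_death_persons: set

    def ground_truth(self) -> dict:
        return {
            "diagnoses": {str(p): code for p, code in sorted(self.diagnoses.items())},
            "diagnosis_dates": {
                str(p): d.isoformat() for p, d in sorted(self.diagnosis_dates.items())
            },
            "metastatic_persons": sorted(self.metastatic_persons),
            "ehr_death_persons": sorted(self.ehr_death_persons),
            "registry_only_death_persons": sorted(self.registry_only_death_persons),
            "planted_regimens": [
                {
                    "person_id": r.person_id,
                    "regimen_concept_id": r.regimen_concept_id,
                    "line_number": r.line_number,
                    "cycle_starts": [d.isoformat() for d in r.cycle_starts],
                }
                for r in self.planted_regimens
            ],
        }


def simulate_patients(
    config: SimulationConfig, out_dir: str | Path | None = None
) -> SimulationResult:
    """Generate a synthetic cohort with planted regimen histories.

    Every planted regimen's exposures are realized in the drug-exposure
    table (component ingredients administered at cycle-length intervals,
    plus optional jitter and co-medication); registry abstracts are written
    for the covered fraction of persons with items consistent with the
    planted diagnosis; ground truth lists the planted regimens, lines and
    diagnoses.  Fully reproducible for a given seed.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    definitions = {d.regimen_concept_id: d for d in default_regimen_definitions()}
    regimen_ids = sorted(config.regimen_frequencies)
    weights = np.array([config.regimen_frequencies[r] for r in regimen_ids], float)
    weights /= weights.sum()

    store = CdmStore()
    result = SimulationResult(store, [], [], {}, {}, set(), set(), set())
    next_exposure = 1

    for person_id in range(1, config.n_persons + 1):
        gender = C.GENDER_MALE if rng.random() < 0.5 else C.GENDER_FEMALE
        store.add_person(Person(person_id, gender, int(rng.integers(1935, 1986))))

        dx_idx = int(rng.random() < 0.4)  # 60% lobular, 40% carcinoma NOS
        combined, site_raw, histology, behavior = DIAGNOSIS_CATALOG[dx_idx]
        dx_date = date(2015, 1, 1) + timedelta(days=int(rng.integers(0, 1096)))
        result.diagnoses[person_id] = combined
        result.diagnosis_dates[person_id] = dx_date
        metastatic = bool(rng.random() < config.fraction_metastatic)
        if metastatic:
            result.metastatic_persons.add(person_id)

        # plant one or two regimens after diagnosis
        n_regimens = 1 + int(rng.random() < config.second_regimen_probability)
        cursor = dx_date + timedelta(days=int(rng.integers(14, 61)))
        for line in range(1, n_regimens + 1):
            regimen_id = int(rng.choice(regimen_ids, p=weights))
            definition = definitions[regimen_id]
            n_cycles = int(rng.integers(config.min_cycles, config.max_cycles + 1))
            cycle_starts: list[date] = []
            start = cursor
            for _ in range(n_cycles):
                jitter = (
                    int(rng.integers(-config.cycle_jitter_days, config.cycle_jitter_days + 1))
                    if config.cycle_jitter_days
                    else 0
                )
                cycle_start = (
                    start
                    if not cycle_starts
                    else cycle_starts[-1]
                    + timedelta(days=definition.cycle_length_days + jitter)
                )
                cycle_starts.append(cycle_start)
                for offset, ingredient in enumerate(sorted(definition.components)):
                    day = cycle_start + timedelta(days=min(offset, 1))
                    store.add_drug_exposure(
                        DrugExposure(
                            next_exposure, person_id, ingredient, day, day, 1.0,
                        )
                    )
                    next_exposure += 1
            result.planted_regimens.append(
                PlantedRegimen(person_id, regimen_id, line, cycle_starts)
            )
            # leave a gap wide enough to force a new line even for a repeat
            cursor = cycle_starts[-1] + timedelta(days=int(rng.integers(100, 151)))

        # co-medication: supportive-care exposures sprinkled over therapy
        if config.comedication_rate > 0:
            planted = [
                r for r in result.planted_regimens if r.person_id == person_id
            ]
            n_onc = sum(
                len(r.cycle_starts) * len(definitions[r.regimen_concept_id].components)
                for r in planted
            )
            n_comed = int(np.round(config.comedication_rate * n_onc))
            span_start = planted[0].cycle_starts[0]
            span_days = max((cursor - span_start).days, 1)
            for _ in range(n_comed):
                day = span_start + timedelta(days=int(rng.integers(0, span_days)))
                drug = C.DEXAMETHASONE if rng.random() < 0.5 else C.ONDANSETRON
                store.add_drug_exposure(
                    DrugExposure(next_exposure, person_id, drug, day, day, 1.0)
                )
                next_exposure += 1

        # deaths: EHR-recorded, registry-only, or none
        u = rng.random()
        last_contact = cursor + timedelta(days=int(rng.integers(30, 181)))
        if u < config.ehr_death_rate:
            result.ehr_death_persons.add(person_id)
            store.deaths.append(DeathRecord(person_id, last_contact, SOURCE_EHR))
        elif u < config.ehr_death_rate + config.registry_extra_death_rate:
            result.registry_only_death_persons.add(person_id)

        covered = rng.random() < config.registry_coverage
        # registry-only deaths are only observable for covered persons
        if person_id in result.registry_only_death_persons and not covered:
            result.registry_only_death_persons.discard(person_id)
        if covered:
            dead = (
                person_id in result.ehr_death_persons
                or person_id in result.registry_only_death_persons
            )
            items = {
                ITEM_PRIMARY_SITE: site_raw,
                ITEM_HISTOLOGY: histology,
                ITEM_BEHAVIOR: behavior,
                ITEM_DATE_OF_DIAGNOSIS: dx_date.strftime("%Y%m%d"),
                ITEM_VITAL_STATUS: "0" if dead else "1",
                ITEM_DATE_OF_LAST_CONTACT: last_contact.strftime("%Y%m%d"),
                ITEM_METASTASIS: "1" if metastatic else "0",
                ITEM_ER_STATUS: "P" if rng.random() < 0.7 else "N",
                ITEM_TUMOR_SIZE: str(int(rng.integers(5, 80))),
            }
            result.registry_records.append(
                RegistryRecord(len(result.registry_records) + 1, person_id, items)
            )

    if out_dir is not None:
        out_dir = Path(out_dir)
        write_cdm(store, out_dir / "cdm")
        write_registry_records(result.registry_records, out_dir / "registry_records.csv")
        write_regimen_definitions(
            default_regimen_definitions(), out_dir / "regimens.csv"
        )
        write_mapping_rules(default_mapping_rules(), out_dir / "mapping_rules.csv")
        (out_dir / "ground_truth.json").write_text(
            json.dumps(result.ground_truth(), indent=1), encoding="utf-8"
        )
        (out_dir / "manifest.json").write_text(
            json.dumps(dataclasses.asdict(config), indent=1), encoding="utf-8"
        )
    return result
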