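"""Clinical-event and episode layers of the oncology CDM.

Holds persons, condition occurrences, modifier measurements (measurements
carrying an explicit link back to the diagnosis they qualify), drug
exposures, deaths, and the EPISODE / EPISODE_EVENT abstraction layer.
Episodes are dated disease or treatment phases (disease first occurrence,
treatment regimen, treatment cycle, ...) that may nest — a regimen episode
contains its cycle episodes — and that link down to the individual clinical
events they were abstracted from.

Dates are whole calendar days and all intervals are closed on both ends.
An episode with ``end_date`` None is ongoing (open on the right).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path

import pandas as pd

from . import concepts as C
from .errors import IntegrityError
from .vocab_store import ConceptGraph

logger = logging.getLogger(__name__)

SOURCE_EHR = "EHR"
SOURCE_REGISTRY = "REGISTRY"


@dataclass
class Person:
    person_id: int
    gender_concept_id: int
    year_of_birth: int


@dataclass
class ConditionOccurrence:
    condition_occurrence_id: int
    person_id: int
    condition_concept_id: int
    start_date: date
    source_code: str = ""


@dataclass
class ModifierMeasurement:
    """A diagnostic modifier (stage, biomarker, tumor size, ...) stored as a
    measurement with an explicit link to the diagnosis it qualifies."""

    measurement_id: int
    person_id: int
    measurement_concept_id: int
    value_concept_id: int | None = None
    value_number: float | None = None
    units: str | None = None
    modifier_of_event_id: int | None = None
    modifier_of_field_concept_id: int | None = None


@dataclass
class DrugExposure:
    drug_exposure_id: int
    person_id: int
    drug_concept_id: int
    start_date: date
    end_date: date
    quantity: float | None = None
    ingredient_concept_id: int | None = None


@dataclass
class Episode:
    """Abstracted disease/treatment interval.

    ``episode_concept_id`` names the abstraction (e.g. Treatment Regimen);
    ``episode_object_concept_id`` names the specific diagnosis or regimen;
    ``episode_number`` is the cycle ordinal for cycles and the line of
    therapy for regimen episodes.
    """

    episode_id: int
    person_id: int
    episode_concept_id: int
    episode_object_concept_id: int
    start_date: date
    end_date: date | None = None
    episode_parent_id: int | None = None
    episode_number: int | None = None


@dataclass(frozen=True)
class EpisodeEvent:
    episode_id: int
    event_id: int
    event_field_concept_id: int


@dataclass(frozen=True)
class DeathRecord:
    person_id: int
    death_date: date
    source: str  # EHR or REGISTRY


@dataclass
class AugmentationReport:
    """Outcome of registry/EHR death reconciliation."""

    ehr_deaths: int
    additional_deaths: int
    percent_increase: float
    conflicting_persons: list[int] = field(default_factory=list)


class CdmStore:
    """In-memory CDM instance with referential-integrity enforcement.

    A :class:`ConceptGraph` may be attached to additionally check concept
    domains; without one, only cross-table references are validated.
    """

    def __init__(self, graph: ConceptGraph | None = None):
        self.graph = graph
        self.persons: dict[int, Person] = {}
        self.conditions: dict[int, ConditionOccurrence] = {}
        self.measurements: dict[int, ModifierMeasurement] = {}
        self.drug_exposures: dict[int, DrugExposure] = {}
        self.episodes: dict[int, Episode] = {}
        self.episode_events: list[EpisodeEvent] = []
        self.deaths: list[DeathRecord] = []

    # -- id helpers --------------------------------------------------------

    def next_id(self, table: dict) -> int:
        return max(table, default=0) + 1

    def _require_person(self, person_id: int) -> Person:
        try:
            return self.persons[person_id]
        except KeyError:
            raise IntegrityError(f"unknown person_id {person_id}") from None

    # -- row insertion -----------------------------------------------------

    def add_person(self, person: Person) -> Person:
        if person.person_id in self.persons:
            raise IntegrityError(f"duplicate person_id {person.person_id}")
        self.persons[person.person_id] = person
        return person

    def add_condition(self, cond: ConditionOccurrence) -> ConditionOccurrence:
        self._require_person(cond.person_id)
        if cond.condition_occurrence_id in self.conditions:
            raise IntegrityError(
                f"duplicate condition_occurrence_id {cond.condition_occurrence_id}"
            )
        if self.graph is not None:
            concept = self.graph.get(cond.condition_concept_id)
            if concept is not None and concept.domain_id != "Condition":
                raise IntegrityError(
                    f"concept {cond.condition_concept_id} is not in the "
                    "Condition domain"
                )
        self.conditions[cond.condition_occurrence_id] = cond
        return cond

    def add_drug_exposure(self, exp: DrugExposure) -> DrugExposure:
        self._require_person(exp.person_id)
        if exp.start_date > exp.end_date:
            raise IntegrityError(
                f"drug_exposure {exp.drug_exposure_id}: start after end"
            )
        if exp.drug_exposure_id in self.drug_exposures:
            raise IntegrityError(
                f"duplicate drug_exposure_id {exp.drug_exposure_id}"
            )
        self.drug_exposures[exp.drug_exposure_id] = exp
        return exp

    # -- modifier linkage --------------------------------------------------

    def _resolve_event(
        self, event_id: int, field_concept_id: int
    ) -> tuple[int, date]:
        """Return (person_id, event date) for a linked event."""
        if field_concept_id == C.FIELD_CONDITION_OCCURRENCE:
            row = self.conditions.get(event_id)
            if row is None:
                raise IntegrityError(f"unknown condition_occurrence {event_id}")
            return row.person_id, row.start_date
        if field_concept_id == C.FIELD_DRUG_EXPOSURE:
            exp = self.drug_exposures.get(event_id)
            if exp is None:
                raise IntegrityError(f"unknown drug_exposure {event_id}")
            return exp.person_id, exp.start_date
        if field_concept_id == C.FIELD_EPISODE:
            ep = self.episodes.get(event_id)
            if ep is None:
                raise IntegrityError(f"unknown episode {event_id}")
            return ep.person_id, ep.start_date
        raise IntegrityError(
            f"unknown table field concept {field_concept_id}"
        )

    def attach_modifier(self, m: ModifierMeasurement) -> ModifierMeasurement:
        """Store a modifier measurement with both linkage fields set.

        The referenced diagnosis (or episode) must exist and belong to the
        same person; exactly one of value_concept_id / value_number is set.
        """
        self._require_person(m.person_id)
        if (m.value_concept_id is None) == (m.value_number is None):
            raise IntegrityError(
                f"measurement {m.measurement_id}: exactly one of "
                "value_concept_id / value_number must be set"
            )
        if m.modifier_of_event_id is None or m.modifier_of_field_concept_id is None:
            raise IntegrityError(
                f"measurement {m.measurement_id}: modifier linkage fields "
                "must both be set"
            )
        person_id, _ = self._resolve_event(
            m.modifier_of_event_id, m.modifier_of_field_concept_id
        )
        if person_id != m.person_id:
            raise IntegrityError(
                f"measurement {m.measurement_id} links to an event of "
                f"person {person_id}, not person {m.person_id}"
            )
        if m.measurement_id in self.measurements:
            raise IntegrityError(f"duplicate measurement_id {m.measurement_id}")
        self.measurements[m.measurement_id] = m
        return m

    def modifiers_of(
        self, event_id: int, field_concept_id: int = C.FIELD_CONDITION_OCCURRENCE
    ) -> list[ModifierMeasurement]:
        return [
            m
            for m in self.measurements.values()
            if m.modifier_of_event_id == event_id
            and m.modifier_of_field_concept_id == field_concept_id
        ]

    # -- episodes ----------------------------------------------------------

    def add_episode(self, ep: Episode) -> Episode:
        self._require_person(ep.person_id)
        if ep.episode_id in self.episodes:
            raise IntegrityError(f"duplicate episode_id {ep.episode_id}")
        if ep.end_date is not None and ep.start_date > ep.end_date:
            raise IntegrityError(f"episode {ep.episode_id}: start after end")
        if ep.episode_number is not None and ep.episode_number < 1:
            raise IntegrityError(
                f"episode {ep.episode_id}: episode_number must be >= 1"
            )
        if ep.episode_parent_id is not None:
            parent = self.episodes.get(ep.episode_parent_id)
            if parent is None:
                raise IntegrityError(
                    f"episode {ep.episode_id}: unknown parent "
                    f"{ep.episode_parent_id}"
                )
            if parent.person_id != ep.person_id:
                raise IntegrityError(
                    f"episode {ep.episode_id}: parent belongs to another person"
                )
            if ep.start_date < parent.start_date or (
                parent.end_date is not None
                and (ep.end_date is None or ep.end_date > parent.end_date)
            ):
                raise IntegrityError(
                    f"episode {ep.episode_id}: interval not contained in "
                    f"parent {parent.episode_id}"
                )
        self.episodes[ep.episode_id] = ep
        return ep

    def create_episode(self, **fields) -> Episode:
        fields.setdefault("episode_id", self.next_id(self.episodes))
        return self.add_episode(Episode(**fields))

    def link_event(
        self, episode_id: int, event_id: int, event_field_concept_id: int
    ) -> EpisodeEvent:
        """Link a clinical event to the episode it comprises.

        The event must belong to the episode's person and its (start) date
        must fall inside the episode interval.
        """
        ep = self.episodes.get(episode_id)
        if ep is None:
            raise IntegrityError(f"unknown episode {episode_id}")
        person_id, event_date = self._resolve_event(event_id, event_field_concept_id)
        if person_id != ep.person_id:
            raise IntegrityError(
                f"event {event_id} belongs to person {person_id}, episode "
                f"{episode_id} to person {ep.person_id}"
            )
        if event_date < ep.start_date or (
            ep.end_date is not None and event_date > ep.end_date
        ):
            raise IntegrityError(
                f"event {event_id} dated {event_date} outside episode "
                f"{episode_id} interval"
            )
        link = EpisodeEvent(episode_id, event_id, event_field_concept_id)
        if link not in self.episode_events:
            self.episode_events.append(link)
        return link

    # -- integrity scan ----------------------------------------------------

    def validate(self) -> list[str]:
        """Full referential/containment scan; returns problem descriptions."""
        problems: list[str] = []
        for table, name in (
            (self.conditions, "condition_occurrence"),
            (self.measurements, "measurement"),
            (self.drug_exposures, "drug_exposure"),
            (self.episodes, "episode"),
        ):
            for row_id, row in table.items():
                if row.person_id not in self.persons:
                    problems.append(f"{name} {row_id}: unknown person {row.person_id}")
        # episode forest: parent links acyclic
        for ep in self.episodes.values():
            seen = {ep.episode_id}
            cur = ep
            while cur.episode_parent_id is not None:
                if cur.episode_parent_id in seen:
                    problems.append(f"episode parent cycle at {ep.episode_id}")
                    break
                cur = self.episodes.get(cur.episode_parent_id)
                if cur is None:
                    problems.append(f"episode {ep.episode_id}: dangling parent")
                    break
                seen.add(cur.episode_id)
        for link in self.episode_events:
            ep = self.episodes.get(link.episode_id)
            if ep is None:
                problems.append(f"episode_event: unknown episode {link.episode_id}")
                continue
            try:
                person_id, event_date = self._resolve_event(
                    link.event_id, link.event_field_concept_id
                )
            except IntegrityError as exc:
                problems.append(str(exc))
                continue
            if person_id != ep.person_id:
                problems.append(
                    f"episode_event {link.episode_id}->{link.event_id}: "
                    "person mismatch"
                )
            if event_date < ep.start_date or (
                ep.end_date is not None and event_date > ep.end_date
            ):
                problems.append(
                    f"episode_event {link.episode_id}->{link.event_id}: "
                    "event date outside episode"
                )
        return problems


def attach_modifier(measurement: ModifierMeasurement, store: CdmStore) -> CdmStore:
    store.attach_modifier(measurement)
    return store


def merge_vital_status(
    ehr_deaths: list[DeathRecord], registry_deaths: list[DeathRecord]
) -> tuple[list[DeathRecord], AugmentationReport]:
    """Reconcile EHR and registry death records.

    Union by person; when both sources report a death with different dates
    the earlier date wins (conservative for survival estimation) and the
    person is flagged.  ``additional_deaths`` counts persons known dead only
    to the registry; ``percent_increase`` is 100 x additional / EHR deaths
    (0 with a warning when there are no EHR deaths).
    """

    def _earliest(records: list[DeathRecord]) -> dict[int, DeathRecord]:
        out: dict[int, DeathRecord] = {}
        for r in sorted(records, key=lambda r: (r.person_id, r.death_date)):
            out.setdefault(r.person_id, r)
        return out

    ehr = _earliest(ehr_deaths)
    registry = _earliest(registry_deaths)
    conflicts = sorted(
        p
        for p in ehr.keys() & registry.keys()
        if ehr[p].death_date != registry[p].death_date
    )
    reconciled: list[DeathRecord] = []
    for person_id in sorted(ehr.keys() | registry.keys()):
        e, r = ehr.get(person_id), registry.get(person_id)
        if e is not None and r is not None:
            reconciled.append(e if e.death_date <= r.death_date else r)
        else:
            reconciled.append(e if e is not None else r)
    additional = len(registry.keys() - ehr.keys())
    if ehr:
        percent = 100.0 * additional / len(ehr)
    else:
        if additional:
            logger.warning(
                "no EHR deaths: percent increase defined as 0 despite %d "
                "registry-only deaths",
                additional,
            )
        percent = 0.0
    return reconciled, AugmentationReport(len(ehr), additional, percent, conflicts)


# -- CSV I/O ----------------------------------------------------------------

_TABLE_FILES = {
    "person": "person.csv",
    "condition_occurrence": "condition_occurrence.csv",
    "measurement": "measurement.csv",
    "drug_exposure": "drug_exposure.csv",
    "death": "death.csv",
    "episode": "episode.csv",
    "episode_event": "episode_event.csv",
}


def _opt(value):
    return "" if value is None else value


def write_cdm(store: CdmStore, directory: str | Path) -> None:
    """Write the seven CDM tables as comma-separated files with lower-case
    column names and ISO dates."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    frames = {
        "person": pd.DataFrame(
            [
                (p.person_id, p.gender_concept_id, p.year_of_birth)
                for p in sorted(store.persons.values(), key=lambda p: p.person_id)
            ],
            columns=["person_id", "gender_concept_id", "year_of_birth"],
        ),
        "condition_occurrence": pd.DataFrame(
            [
                (
                    c.condition_occurrence_id,
                    c.person_id,
                    c.condition_concept_id,
                    c.start_date.isoformat(),
                    c.source_code,
                )
                for c in sorted(
                    store.conditions.values(),
                    key=lambda c: c.condition_occurrence_id,
                )
            ],
            columns=[
                "condition_occurrence_id",
                "person_id",
                "condition_concept_id",
                "condition_start_date",
                "condition_source_value",
            ],
        ),
        "measurement": pd.DataFrame(
            [
                (
                    m.measurement_id,
                    m.person_id,
                    m.measurement_concept_id,
                    _opt(m.value_concept_id),
                    _opt(m.value_number),
                    _opt(m.units),
                    _opt(m.modifier_of_event_id),
                    _opt(m.modifier_of_field_concept_id),
                )
                for m in sorted(
                    store.measurements.values(), key=lambda m: m.measurement_id
                )
            ],
            columns=[
                "measurement_id",
                "person_id",
                "measurement_concept_id",
                "value_as_concept_id",
                "value_as_number",
                "unit_source_value",
                "modifier_of_event_id",
                "modifier_of_field_concept_id",
            ],
        ),
        "drug_exposure": pd.DataFrame(
            [
                (
                    d.drug_exposure_id,
                    d.person_id,
                    d.drug_concept_id,
                    _opt(d.ingredient_concept_id),
                    d.start_date.isoformat(),
                    d.end_date.isoformat(),
                    _opt(d.quantity),
                )
                for d in sorted(
                    store.drug_exposures.values(),
                    key=lambda d: d.drug_exposure_id,
                )
            ],
            columns=[
                "drug_exposure_id",
                "person_id",
                "drug_concept_id",
                "ingredient_concept_id",
                "drug_exposure_start_date",
                "drug_exposure_end_date",
                "quantity",
            ],
        ),
        "death": pd.DataFrame(
            [
                (d.person_id, d.death_date.isoformat(), d.source)
                for d in sorted(
                    store.deaths, key=lambda d: (d.person_id, d.death_date)
                )
            ],
            columns=["person_id", "death_date", "death_source"],
        ),
        "episode": pd.DataFrame(
            [
                (
                    e.episode_id,
                    e.person_id,
                    e.episode_concept_id,
                    e.episode_object_concept_id,
                    _opt(e.episode_parent_id),
                    _opt(e.episode_number),
                    e.start_date.isoformat(),
                    "" if e.end_date is None else e.end_date.isoformat(),
                )
                for e in sorted(store.episodes.values(), key=lambda e: e.episode_id)
            ],
            columns=[
                "episode_id",
                "person_id",
                "episode_concept_id",
                "episode_object_concept_id",
                "episode_parent_id",
                "episode_number",
                "episode_start_date",
                "episode_end_date",
            ],
        ),
        "episode_event": pd.DataFrame(
            sorted(
                (
                    (l.episode_id, l.event_id, l.event_field_concept_id)
                    for l in store.episode_events
                ),
            ),
            columns=["episode_id", "event_id", "episode_event_field_concept_id"],
        ),
    }
    for name, frame in frames.items():
        frame.to_csv(directory / _TABLE_FILES[name], index=False)


def _date(value: str) -> date:
    return date.fromisoformat(str(value))


def _opt_int(value) -> int | None:
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return None
    return int(value)


def _opt_float(value) -> float | None:
    if value is None or value == "" or (isinstance(value, float) and pd.isna(value)):
        return None
    return float(value)


def read_cdm(directory: str | Path, graph: ConceptGraph | None = None) -> CdmStore:
    """Load the CDM tables (missing files are treated as empty tables);
    all referential and containment checks run during insertion."""
    directory = Path(directory)
    store = CdmStore(graph)

    def _frame(name: str) -> pd.DataFrame | None:
        path = directory / _TABLE_FILES[name]
        if not path.is_file():
            return None
        return pd.read_csv(path, dtype=str, keep_default_na=False)

    df = _frame("person")
    if df is not None:
        for row in df.itertuples(index=False):
            store.add_person(
                Person(int(row.person_id), int(row.gender_concept_id), int(row.year_of_birth))
            )
    df = _frame("condition_occurrence")
    if df is not None:
        for row in df.itertuples(index=False):
            store.add_condition(
                ConditionOccurrence(
                    int(row.condition_occurrence_id),
                    int(row.person_id),
                    int(row.condition_concept_id),
                    _date(row.condition_start_date),
                    row.condition_source_value,
                )
            )
    df = _frame("drug_exposure")
    if df is not None:
        for row in df.itertuples(index=False):
            store.add_drug_exposure(
                DrugExposure(
                    int(row.drug_exposure_id),
                    int(row.person_id),
                    int(row.drug_concept_id),
                    _date(row.drug_exposure_start_date),
                    _date(row.drug_exposure_end_date),
                    _opt_float(row.quantity),
                    _opt_int(row.ingredient_concept_id),
                )
            )
    df = _frame("episode")
    if df is not None:
        rows = [
            Episode(
                int(row.episode_id),
                int(row.person_id),
                int(row.episode_concept_id),
                int(row.episode_object_concept_id),
                _date(row.episode_start_date),
                None if row.episode_end_date == "" else _date(row.episode_end_date),
                _opt_int(row.episode_parent_id),
                _opt_int(row.episode_number),
            )
            for row in df.itertuples(index=False)
        ]
        # parents may appear after children in the file
        for ep in sorted(rows, key=lambda e: (e.episode_parent_id is not None, e.episode_id)):
            store.add_episode(ep)
    df = _frame("measurement")
    if df is not None:
        for row in df.itertuples(index=False):
            store.attach_modifier(
                ModifierMeasurement(
                    int(row.measurement_id),
                    int(row.person_id),
                    int(row.measurement_concept_id),
                    _opt_int(row.value_as_concept_id),
                    _opt_float(row.value_as_number),
                    row.unit_source_value or None,
                    _opt_int(row.modifier_of_event_id),
                    _opt_int(row.modifier_of_field_concept_id),
                )
            )
    df = _frame("episode_event")
    if df is not None:
        for row in df.itertuples(index=False):
            store.link_event(
                int(row.episode_id),
                int(row.event_id),
                int(row.episode_event_field_concept_id),
            )
    df = _frame("death")
    if df is not None:
        for row in df.itertuples(index=False):
            store.deaths.append(
                DeathRecord(int(row.person_id), _date(row.death_date), row.death_source)
            )
    return store
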