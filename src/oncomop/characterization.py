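"""Treatment-pattern characterization on a conformant CDM instance.

Implements the shape of a metastatic-cancer use case: identify a cohort by
an index diagnosis concept set (expanded through the hierarchy), an optional
diagnostic-modifier requirement (e.g. metastatic status) and an optional
systemic-therapy requirement; then describe the first-line regimen
distribution with category grouping, plus basic demographics and first-line
duration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date

import pandas as pd

from . import concepts as C
from .cdm_core import CdmStore
from .vocab_store import ConceptGraph

UNTREATED = "Untreated"


@dataclass
class CohortDefinition:
    """Cohort entry logic; the index date is the earliest qualifying
    diagnosis, and the observation window runs to the last encounter or the
    fixed cutoff, whichever is first."""

    index_condition_concept_ids: set
    required_modifier: tuple[int, int] | None = None  # (measurement, value concept)
    require_systemic_therapy: bool = False
    observation_cutoff: date | None = None

    def __post_init__(self):
        if not self.index_condition_concept_ids:
            raise ValueError("index concept set must be non-empty")


@dataclass(frozen=True)
class CohortMember:
    person_id: int
    index_date: date
    observation_end: date | None


@dataclass
class TreatmentCategoryMap:
    """Total mapping from regimen concept to a small set of category labels;
    regimens not listed fall into ``other_label``."""

    mapping: dict = field(default_factory=dict)
    other_label: str = "Other"

    def category(self, regimen_concept_id: int) -> str:
        return self.mapping.get(regimen_concept_id, self.other_label)


def _last_event_date(store: CdmStore, person_id: int) -> date | None:
    dates = [
        c.start_date for c in store.conditions.values() if c.person_id == person_id
    ]
    dates += [
        d.end_date for d in store.drug_exposures.values() if d.person_id == person_id
    ]
    dates += [
        e.end_date or e.start_date
        for e in store.episodes.values()
        if e.person_id == person_id
    ]
    return max(dates) if dates else None


def _regimen_episodes(store: CdmStore, person_id: int):
    return sorted(
        (
            e
            for e in store.episodes.values()
            if e.person_id == person_id
            and e.episode_concept_id == C.TREATMENT_REGIMEN
        ),
        key=lambda e: (e.start_date, e.episode_id),
    )


def identify_cohort(
    defn: CohortDefinition, store: CdmStore, graph: ConceptGraph
) -> list[CohortMember]:
    """Persons with a qualifying index diagnosis (descendant expansion),
    satisfying the modifier and therapy requirements."""
    index_set: set[int] = set()
    for cid in defn.index_condition_concept_ids:
        index_set |= graph.descendants_of(cid)

    members = []
    for person_id in sorted(store.persons):
        qualifying = [
            c
            for c in store.conditions.values()
            if c.person_id == person_id and c.condition_concept_id in index_set
        ]
        if not qualifying:
            continue
        if defn.required_modifier is not None:
            meas_id, value_id = defn.required_modifier
            condition_ids = {c.condition_occurrence_id for c in qualifying}
            has_modifier = any(
                m.measurement_concept_id == meas_id
                and m.value_concept_id == value_id
                and m.modifier_of_field_concept_id == C.FIELD_CONDITION_OCCURRENCE
                and m.modifier_of_event_id in condition_ids
                for m in store.measurements.values()
            )
            if not has_modifier:
                continue
        index_date = min(c.start_date for c in qualifying)
        if defn.require_systemic_therapy:
            regimens = [
                e
                for e in _regimen_episodes(store, person_id)
                if e.start_date >= index_date
            ]
            if not regimens:
                continue
        last = _last_event_date(store, person_id)
        if defn.observation_cutoff is not None:
            observation_end = (
                min(last, defn.observation_cutoff)
                if last is not None
                else defn.observation_cutoff
            )
        else:
            observation_end = last
        members.append(CohortMember(person_id, index_date, observation_end))
    return members


def _median(values: list[float]) -> float | None:
    """Average of the two central order statistics."""
    if not values:
        return None
    ordered = sorted(values)
    n = len(ordered)
    mid = n // 2
    if n % 2:
        return float(ordered[mid])
    return (ordered[mid - 1] + ordered[mid]) / 2.0


def first_line_distribution(
    cohort: list[CohortMember],
    store: CdmStore,
    categories: TreatmentCategoryMap,
) -> tuple[pd.DataFrame, dict]:
    """Distribution of first-line regimens over treatment categories.

    Per person the first line is the earliest treatment-regimen episode on
    or after the index date; members without one count as ``Untreated``.
    Returns the (category, n, percent) table plus summary statistics:
    median age at index (index year minus birth year), percent male, and
    median first-line duration in days (closed interval length).
    """
    counts: dict[str, int] = {}
    durations: list[float] = []
    ages: list[float] = []
    males = 0
    for member in cohort:
        person = store.persons[member.person_id]
        ages.append(member.index_date.year - person.year_of_birth)
        if person.gender_concept_id == C.GENDER_MALE:
            males += 1
        first_line = next(
            (
                e
                for e in _regimen_episodes(store, member.person_id)
                if e.start_date >= member.index_date
            ),
            None,
        )
        if first_line is None:
            category = UNTREATED
        else:
            category = categories.category(first_line.episode_object_concept_id)
            if first_line.end_date is not None:
                durations.append(
                    (first_line.end_date - first_line.start_date).days + 1
                )
        counts[category] = counts.get(category, 0) + 1

    total = sum(counts.values())
    table = pd.DataFrame(
        [
            {"category": cat, "n": n, "percent": 100.0 * n / total}
            for cat, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        ],
        columns=["category", "n", "percent"],
    )
    summaries = {
        "n_persons": total,
        "median_age_at_index": _median(ages),
        "percent_male": 100.0 * males / total if total else None,
        "median_first_line_duration_days": _median(durations),
    }
    return table, summaries
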