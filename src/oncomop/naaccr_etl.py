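"""Vocabulary-driven transformation of tumor-registry abstracts into the CDM.

A registry abstract is one row per tumor keyed by NAACCR item numbers
(primary site 400, histology 522, behavior 523, date of diagnosis 390,
vital status 1760, date of last contact 1750, plus modifier items).  The
transformation is driven by data, not code: a list of item-mapping rules
says, per item, whether it contributes a diagnosis component, a categorical
or numeric modifier measurement, or vital status, and how raw values map to
vocabulary concepts.

For each record the diagnosis triple is assembled into a combined ICD-O-3
code, looked up among the precoordinated concepts, and written as a
condition occurrence carrying the designated standard concept; mapped
modifier items become measurements explicitly linked to that condition; a
Disease First Occurrence episode anchors the diagnosis; and registry vital
status becomes a registry death record for later reconciliation with EHR
deaths.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Iterable, Sequence

from . import concepts as C
from .cdm_core import (
    CdmStore,
    ConditionOccurrence,
    DeathRecord,
    ModifierMeasurement,
    SOURCE_REGISTRY,
)
from .errors import MappingError
from .vocab_store import ConceptGraph, Rel

logger = logging.getLogger(__name__)

ITEM_PRIMARY_SITE = "400"
ITEM_HISTOLOGY = "522"
ITEM_BEHAVIOR = "523"
ITEM_DATE_OF_DIAGNOSIS = "390"
ITEM_DATE_OF_LAST_CONTACT = "1750"
ITEM_VITAL_STATUS = "1760"

REQUIRED_ITEMS = (
    ITEM_PRIMARY_SITE,
    ITEM_HISTOLOGY,
    ITEM_BEHAVIOR,
    ITEM_DATE_OF_DIAGNOSIS,
)

KIND_DIAGNOSIS_COMPONENT = "DIAGNOSIS_COMPONENT"
KIND_MODIFIER_CATEGORICAL = "MODIFIER_CATEGORICAL"
KIND_MODIFIER_NUMERIC = "MODIFIER_NUMERIC"
KIND_VITAL_STATUS = "VITAL_STATUS"
KIND_DATE = "DATE"

STATUS_MAPPED = "mapped"
STATUS_UNMAPPED = "unmapped"
STATUS_REJECTED = "rejected"

VITAL_DEAD = "DEAD"
VITAL_ALIVE = "ALIVE"


@dataclass(frozen=True)
class RegistryRecord:
    record_id: int
    person_id: int
    items: dict  # item number (str) -> raw value (str)


@dataclass(frozen=True)
class ItemMappingRule:
    item_number: str
    kind: str
    measurement_concept_id: int | None = None
    value_map: dict | None = None  # raw value -> value concept id (or DEAD/ALIVE)
    units: str | None = None

    def __post_init__(self):
        if self.kind == KIND_MODIFIER_CATEGORICAL and not self.value_map:
            raise ValueError(f"item {self.item_number}: categorical rule needs a value_map")
        if self.kind == KIND_MODIFIER_NUMERIC and not self.units:
            raise ValueError(f"item {self.item_number}: numeric rule needs units")


@dataclass
class RecordReport:
    record_id: int
    status: str
    reason: str = ""
    condition_concept_id: int | None = None
    skipped_items: dict = field(default_factory=dict)  # item -> count
    partial_date: bool = False


@dataclass
class EtlResult:
    store: CdmStore
    reports: list[RecordReport]
    registry_deaths: list[DeathRecord]

    @property
    def run_report(self) -> dict:
        mapped = sum(r.status == STATUS_MAPPED for r in self.reports)
        unmapped = sum(r.status == STATUS_UNMAPPED for r in self.reports)
        rejected = sum(r.status == STATUS_REJECTED for r in self.reports)
        report = {
            "records_in": len(self.reports),
            "mapped": mapped,
            "unmapped": unmapped,
            "rejected": rejected,
        }
        if mapped + unmapped:
            report["coverage"] = coverage_report(self.reports)
        return report


def normalize_site(raw: str) -> str:
    """NAACCR primary site values carry no dot (``C509``); restore it."""
    raw = raw.strip().upper()
    if len(raw) == 4 and raw.startswith("C") and "." not in raw:
        return f"{raw[:3]}.{raw[3]}"
    return raw


def parse_naaccr_date(raw: str) -> tuple[date, bool]:
    """Parse YYYYMMDD; a year-only partial date resolves to July 1 and is
    flagged.  Returns (date, was_partial)."""
    raw = raw.strip()
    if len(raw) == 8 and raw.isdigit():
        return date(int(raw[:4]), int(raw[4:6]), int(raw[6:8])), False
    if len(raw) == 4 and raw.isdigit():
        return date(int(raw), 7, 1), True
    raise MappingError(f"unparseable NAACCR date {raw!r}")


def _standard_for(combined_code: str, graph: ConceptGraph) -> int | None:
    """The designated standard concept for a precoordinated code, or None."""
    concept = graph.by_code("ICDO3", combined_code)
    if concept is None:
        return None
    mapped = graph.targets(concept.concept_id, Rel.MAPS_TO)
    if mapped:
        return min(mapped)
    if concept.standard:
        return concept.concept_id
    return None


def transform_record(
    record: RegistryRecord,
    rules: Sequence[ItemMappingRule],
    graph: ConceptGraph,
    store: CdmStore,
) -> RecordReport:
    """Transform one registry abstract; see module docstring for the steps.

    Returns a per-record report: ``mapped`` when the diagnosis resolved to a
    standard concept, ``unmapped`` when the combined code is unknown or not
    integrated, ``rejected`` when required items are missing.
    """
    items = {k: v for k, v in record.items.items() if str(v).strip() != ""}
    missing = [item for item in REQUIRED_ITEMS if item not in items]
    if missing:
        return RecordReport(
            record.record_id,
            STATUS_REJECTED,
            reason=f"missing required item(s) {','.join(missing)}",
        )

    site = normalize_site(items[ITEM_PRIMARY_SITE])
    combined = f"{items[ITEM_HISTOLOGY].strip()}/{items[ITEM_BEHAVIOR].strip()}-{site}"
    try:
        dx_date, partial = parse_naaccr_date(items[ITEM_DATE_OF_DIAGNOSIS])
    except MappingError as exc:
        return RecordReport(record.record_id, STATUS_REJECTED, reason=str(exc))

    standard_id = _standard_for(combined, graph)
    report = RecordReport(
        record.record_id, STATUS_MAPPED, condition_concept_id=standard_id,
        partial_date=partial,
    )
    if standard_id is None:
        report.status = STATUS_UNMAPPED
        report.reason = f"no standard concept for combined code {combined}"
        return report

    condition = store.add_condition(
        ConditionOccurrence(
            condition_occurrence_id=store.next_id(store.conditions),
            person_id=record.person_id,
            condition_concept_id=standard_id,
            start_date=dx_date,
            source_code=combined,
        )
    )

    for rule in rules:
        raw = items.get(rule.item_number)
        if raw is None:
            continue
        raw = raw.strip()
        if rule.kind == KIND_MODIFIER_CATEGORICAL:
            value_id = rule.value_map.get(raw)
            if value_id is None:
                report.skipped_items[rule.item_number] = (
                    report.skipped_items.get(rule.item_number, 0) + 1
                )
                continue
            store.attach_modifier(
                ModifierMeasurement(
                    measurement_id=store.next_id(store.measurements),
                    person_id=record.person_id,
                    measurement_concept_id=rule.measurement_concept_id,
                    value_concept_id=int(value_id),
                    modifier_of_event_id=condition.condition_occurrence_id,
                    modifier_of_field_concept_id=C.FIELD_CONDITION_OCCURRENCE,
                )
            )
        elif rule.kind == KIND_MODIFIER_NUMERIC:
            try:
                value = float(raw)
            except ValueError:
                report.skipped_items[rule.item_number] = (
                    report.skipped_items.get(rule.item_number, 0) + 1
                )
                continue
            store.attach_modifier(
                ModifierMeasurement(
                    measurement_id=store.next_id(store.measurements),
                    person_id=record.person_id,
                    measurement_concept_id=rule.measurement_concept_id,
                    value_number=value,
                    units=rule.units,
                    modifier_of_event_id=condition.condition_occurrence_id,
                    modifier_of_field_concept_id=C.FIELD_CONDITION_OCCURRENCE,
                )
            )

    store.create_episode(
        person_id=record.person_id,
        episode_concept_id=C.DISEASE_FIRST_OCCURRENCE,
        episode_object_concept_id=standard_id,
        start_date=dx_date,
        end_date=None,
    )
    return report


def _registry_death(
    record: RegistryRecord, rules: Sequence[ItemMappingRule]
) -> DeathRecord | None:
    vital_rule = next((r for r in rules if r.kind == KIND_VITAL_STATUS), None)
    if vital_rule is None:
        return None
    raw = str(record.items.get(vital_rule.item_number, "")).strip()
    if not raw or vital_rule.value_map.get(raw) != VITAL_DEAD:
        return None
    raw_date = str(record.items.get(ITEM_DATE_OF_LAST_CONTACT, "")).strip()
    if not raw_date:
        logger.warning(
            "record %s reports death but no date of last contact; skipped",
            record.record_id,
        )
        return None
    death_date, _ = parse_naaccr_date(raw_date)
    return DeathRecord(record.person_id, death_date, SOURCE_REGISTRY)


def run_etl(
    records: Iterable[RegistryRecord],
    rules: Sequence[ItemMappingRule],
    graph: ConceptGraph,
    store: CdmStore,
) -> EtlResult:
    """Transform every record and collect registry death records."""
    reports: list[RecordReport] = []
    registry_deaths: list[DeathRecord] = []
    for record in records:
        reports.append(transform_record(record, rules, graph, store))
        death = _registry_death(record, rules)
        if death is not None:
            registry_deaths.append(death)
    return EtlResult(store, reports, registry_deaths)


def coverage_report(reports: Sequence[RecordReport]) -> float:
    """Fraction of processable records whose diagnosis mapped to a standard
    concept (the registry diagnosis-coverage metric)."""
    mapped = sum(r.status == STATUS_MAPPED for r in reports)
    unmapped = sum(r.status == STATUS_UNMAPPED for r in reports)
    if mapped + unmapped == 0:
        raise MappingError("no processable registry records")
    return mapped / (mapped + unmapped)


# -- file I/O ----------------------------------------------------------------


def read_registry_records(path: str | Path) -> list[RegistryRecord]:
    """Item-number-keyed CSV: columns ``record_id``, ``person_id`` and one
    column per NAACCR item number."""
    out = []
    with Path(path).open(newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            items = {
                k: v
                for k, v in row.items()
                if k not in ("record_id", "person_id") and v != ""
            }
            out.append(
                RegistryRecord(int(row["record_id"]), int(row["person_id"]), items)
            )
    return out


def write_registry_records(
    records: Iterable[RegistryRecord], path: str | Path
) -> None:
    records = list(records)
    item_columns = sorted({k for r in records for k in r.items}, key=lambda s: (len(s), s))
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(["record_id", "person_id", *item_columns])
        for r in sorted(records, key=lambda r: r.record_id):
            w.writerow(
                [r.record_id, r.person_id, *(r.items.get(c, "") for c in item_columns)]
            )


def load_mapping_rules(path: str | Path) -> list[ItemMappingRule]:
    """Rule CSV: item_number, kind, measurement_concept_id, units, value_map
    (``raw:mapped`` pairs separated by ``;``)."""
    out = []
    with Path(path).open(newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            value_map = None
            if row.get("value_map"):
                value_map = dict(
                    pair.split(":", 1) for pair in row["value_map"].split(";") if pair
                )
                if row["kind"] == KIND_MODIFIER_CATEGORICAL:
                    value_map = {k: int(v) for k, v in value_map.items()}
            out.append(
                ItemMappingRule(
                    item_number=row["item_number"],
                    kind=row["kind"],
                    measurement_concept_id=(
                        int(row["measurement_concept_id"])
                        if row.get("measurement_concept_id")
                        else None
                    ),
                    value_map=value_map,
                    units=row.get("units") or None,
                )
            )
    return out


def write_mapping_rules(rules: Iterable[ItemMappingRule], path: str | Path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(["item_number", "kind", "measurement_concept_id", "units", "value_map"])
        for r in rules:
            value_map = (
                ";".join(f"{k}:{v}" for k, v in sorted(r.value_map.items()))
                if r.value_map
                else ""
            )
            w.writerow(
                [r.item_number, r.kind, r.measurement_concept_id or "", r.units or "", value_map]
            )
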