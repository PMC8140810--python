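"""Rule-based chemotherapy-regimen detection from drug-exposure records.

The algorithm matches drug ingredients and their timing against a catalog of
regimen definitions (a regimen = a named set of component ingredients plus a
cycle length, in the style of the HemOnc ontology):

1. *Normalization* — every exposure is resolved to its RxNorm-style
   ingredient through the vocabulary; exposures to drugs outside the
   antineoplastic class are flagged and excluded from matching.
2. *Era construction* — per person and ingredient, exposures separated by at
   most ``era_gap_days`` merge into continuous ingredient eras.
3. *Cycle detection* — administration start dates are grouped greedily from
   the left: a cycle opens at the earliest unconsumed start and absorbs all
   starts within ``cycle_window_days``.
4. *Regimen matching* — each cycle's ingredient set is matched to a
   definition, preferring exact set equality, then the largest definition
   fully contained in the observed set (tolerates co-medication; a
   definition with a missing component never matches).
5. *Assembly* — consecutive cycles matched to the same regimen, separated by
   at most ``max_cycle_gap_days``, merge into one detected regimen; lines of
   therapy are numbered per person in start order, with a new line whenever
   the regimen changes or the gap is exceeded.

Dosing is not used for matching in this version; quantity is carried through
for reporting only.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from datetime import date, timedelta
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from . import concepts as C
from .cdm_core import CdmStore, DrugExposure
from .errors import IntegrityError
from .vocab_store import ConceptGraph, Rel

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RegimenDefinition:
    regimen_concept_id: int
    name: str
    components: frozenset[int]
    cycle_length_days: int

    def __post_init__(self):
        if not self.components:
            raise ValueError(f"regimen {self.regimen_concept_id}: empty components")
        if self.cycle_length_days < 1:
            raise ValueError(
                f"regimen {self.regimen_concept_id}: cycle_length_days must be >= 1"
            )


@dataclass
class IngredientEra:
    """Merged interval of consecutive exposures to one ingredient."""

    person_id: int
    ingredient_concept_id: int
    start_date: date
    end_date: date
    exposure_ids: list[int] = field(default_factory=list)


@dataclass(frozen=True)
class Cycle:
    person_id: int
    start_date: date
    ingredients: frozenset[int]
    exposure_ids: tuple[int, ...]


@dataclass
class DetectedRegimen:
    person_id: int
    regimen_concept_id: int
    start_date: date
    end_date: date
    cycles: list[tuple[int, date, frozenset[int]]]  # (cycle_number, start, ingredients)
    line_number: int
    cycle_exposure_ids: tuple[tuple[int, ...], ...] = ()


@dataclass
class DetectionConfig:
    """Tunable thresholds; defaults follow common oncology-analytics practice."""

    era_gap_days: int = 30
    cycle_window_days: int = 14
    max_cycle_gap_days: int = 90
    require_exact_match: bool = False
    antineoplastic_root: int = C.ANTINEOPLASTIC_AGENT


@dataclass
class NormalizationResult:
    exposures: list[DrugExposure]
    non_oncologic_ids: set[int]
    dropped: int


def load_regimen_definitions(path: str | Path) -> list[RegimenDefinition]:
    """Read a regimen-definition CSV: regimen_concept_id, regimen_name,
    component_ingredient_ids (semicolon-separated), cycle_length_days."""
    out = []
    with Path(path).open(newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            out.append(
                RegimenDefinition(
                    int(row["regimen_concept_id"]),
                    row["regimen_name"],
                    frozenset(
                        int(x) for x in row["component_ingredient_ids"].split(";") if x
                    ),
                    int(row["cycle_length_days"]),
                )
            )
    return out


def write_regimen_definitions(
    definitions: Iterable[RegimenDefinition], path: str | Path
) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(
            ["regimen_concept_id", "regimen_name", "component_ingredient_ids", "cycle_length_days"]
        )
        for d in sorted(definitions, key=lambda d: d.regimen_concept_id):
            w.writerow(
                [
                    d.regimen_concept_id,
                    d.name,
                    ";".join(str(i) for i in sorted(d.components)),
                    d.cycle_length_days,
                ]
            )


# -- step 1: normalization ---------------------------------------------------


def _resolve_ingredient(drug_concept_id: int, graph: ConceptGraph) -> int | None:
    concept = graph.get(drug_concept_id)
    if concept is None:
        return None
    candidates = [drug_concept_id] + graph.targets(drug_concept_id, Rel.MAPS_TO)
    for cid in candidates:
        c = graph.get(cid)
        if c is not None and c.concept_class_id == "Ingredient":
            return cid
    # climb the drug hierarchy from any candidate to an ingredient
    for cid in candidates:
        if cid not in graph:
            continue
        ingredients = sorted(
            a
            for a in graph.ancestors_of(cid)
            if graph.concept(a).concept_class_id == "Ingredient"
        )
        if ingredients:
            return ingredients[0]
    return None


def normalize_to_ingredients(
    exposures: Iterable[DrugExposure],
    graph: ConceptGraph,
    antineoplastic_root: int = C.ANTINEOPLASTIC_AGENT,
) -> NormalizationResult:
    """Resolve every exposure to its ingredient.

    Exposures whose drug concept cannot be resolved are dropped (counted);
    exposures whose ingredient is not an antineoplastic are kept but flagged
    so that matching can ignore them.
    """
    onc_ingredients: set[int] | None = None
    if antineoplastic_root in graph:
        onc_ingredients = graph.descendants_of(antineoplastic_root)
    resolved: list[DrugExposure] = []
    non_oncologic: set[int] = set()
    dropped = 0
    for exp in exposures:
        ingredient = _resolve_ingredient(exp.drug_concept_id, graph)
        if ingredient is None:
            dropped += 1
            continue
        resolved.append(replace(exp, ingredient_concept_id=ingredient))
        if onc_ingredients is not None and ingredient not in onc_ingredients:
            non_oncologic.add(exp.drug_exposure_id)
    if dropped:
        logger.warning("dropped %d exposures with unmappable drug concepts", dropped)
    return NormalizationResult(resolved, non_oncologic, dropped)


# -- step 2: eras ------------------------------------------------------------


def build_eras(
    exposures: Iterable[DrugExposure], gap_days: int = 30
) -> list[IngredientEra]:
    """Merge per person+ingredient exposures whose gaps are <= gap_days."""
    ordered = sorted(
        exposures,
        key=lambda e: (
            e.person_id,
            e.ingredient_concept_id or e.drug_concept_id,
            e.start_date,
            e.drug_exposure_id,
        ),
    )
    eras: list[IngredientEra] = []
    for exp in ordered:
        ingredient = exp.ingredient_concept_id or exp.drug_concept_id
        last = eras[-1] if eras else None
        if (
            last is not None
            and last.person_id == exp.person_id
            and last.ingredient_concept_id == ingredient
            and (exp.start_date - last.end_date).days <= gap_days
        ):
            last.end_date = max(last.end_date, exp.end_date)
            last.exposure_ids.append(exp.drug_exposure_id)
        else:
            eras.append(
                IngredientEra(
                    exp.person_id,
                    ingredient,
                    exp.start_date,
                    exp.end_date,
                    [exp.drug_exposure_id],
                )
            )
    return eras


# -- step 3: cycles ----------------------------------------------------------


def detect_cycles(
    eras: Sequence[IngredientEra],
    window_days: int = 14,
    exposures_by_id: Mapping[int, DrugExposure] | None = None,
) -> list[Cycle]:
    """Greedy left-to-right grouping of administration starts into cycles.

    The administrations are the constituent exposure starts of the eras
    (when an exposure lookup is given) or the era starts themselves.  A
    cycle opens at the earliest unconsumed start and absorbs every start
    within ``window_days``; each start is consumed exactly once.
    """
    if not eras:
        return []
    person_ids = {e.person_id for e in eras}
    if len(person_ids) != 1:
        raise ValueError("detect_cycles expects eras for a single person")
    person_id = person_ids.pop()

    events: list[tuple[date, int, int]] = []  # (start, ingredient, exposure_id)
    for era in eras:
        if exposures_by_id is None:
            events.append((era.start_date, era.ingredient_concept_id, era.exposure_ids[0]))
        else:
            for eid in era.exposure_ids:
                events.append(
                    (exposures_by_id[eid].start_date, era.ingredient_concept_id, eid)
                )
    events.sort()

    cycles: list[Cycle] = []
    i = 0
    while i < len(events):
        open_date = events[i][0]
        members = []
        j = i
        while j < len(events) and (events[j][0] - open_date).days <= window_days:
            members.append(events[j])
            j += 1
        cycles.append(
            Cycle(
                person_id,
                open_date,
                frozenset(m[1] for m in members),
                tuple(sorted(m[2] for m in members)),
            )
        )
        i = j
    return cycles


# -- step 4: matching --------------------------------------------------------


def match_regimen(
    cycle_ingredients: frozenset[int] | set[int],
    definitions: Sequence[RegimenDefinition],
    require_exact: bool = False,
) -> int | None:
    """Match a cycle's ingredient set to a regimen definition.

    Exact set equality wins; otherwise the definition that is a maximal
    subset of the observed ingredients (tolerating co-medication).  Ties go
    to the lowest regimen id with a warning.
    """
    if not definitions:
        raise ValueError("no regimen definitions supplied")
    observed = frozenset(cycle_ingredients)
    exact = sorted(
        d.regimen_concept_id for d in definitions if d.components == observed
    )
    if exact:
        if len(exact) > 1:
            logger.warning("multiple exact regimen matches %s; choosing %s", exact, exact[0])
        return exact[0]
    if require_exact:
        return None
    subsets = [d for d in definitions if d.components < observed]
    if not subsets:
        return None
    best_size = max(len(d.components) for d in subsets)
    best = sorted(
        d.regimen_concept_id for d in subsets if len(d.components) == best_size
    )
    if len(best) > 1:
        logger.warning("tied subset regimen matches %s; choosing %s", best, best[0])
    return best[0]


# -- step 5: assembly --------------------------------------------------------


def assemble_regimens(
    matched_cycles: Sequence[tuple[Cycle, int | None]],
    definitions: Sequence[RegimenDefinition],
    max_cycle_gap_days: int = 90,
    index_dates: Mapping[int, date] | None = None,
) -> list[DetectedRegimen]:
    """Merge consecutive same-regimen cycles into detected regimens and
    assign lines of therapy.

    Unmatched cycles are skipped.  The regimen end is the last cycle start
    plus the cycle length minus one.  Line numbers restart at the first
    regimen on/after the person's index date when one is supplied.
    """
    defs = {d.regimen_concept_id: d for d in definitions}
    by_person: dict[int, list[tuple[Cycle, int]]] = {}
    for cycle, regimen_id in matched_cycles:
        if regimen_id is None:
            continue
        by_person.setdefault(cycle.person_id, []).append((cycle, regimen_id))

    detected: list[DetectedRegimen] = []
    for person_id in sorted(by_person):
        rows = sorted(by_person[person_id], key=lambda t: t[0].start_date)
        groups: list[list[tuple[Cycle, int]]] = []
        for row in rows:
            cycle, regimen_id = row
            if (
                groups
                and groups[-1][-1][1] == regimen_id
                and (cycle.start_date - groups[-1][-1][0].start_date).days
                <= max_cycle_gap_days
            ):
                groups[-1].append(row)
            else:
                groups.append([row])

        person_regimens = []
        for group in groups:
            regimen_id = group[0][1]
            cycle_len = defs[regimen_id].cycle_length_days
            last_start = group[-1][0].start_date
            person_regimens.append(
                DetectedRegimen(
                    person_id=person_id,
                    regimen_concept_id=regimen_id,
                    start_date=group[0][0].start_date,
                    end_date=last_start + timedelta(days=cycle_len - 1),
                    cycles=[
                        (i + 1, c.start_date, c.ingredients)
                        for i, (c, _) in enumerate(group)
                    ],
                    line_number=0,
                    cycle_exposure_ids=tuple(c.exposure_ids for c, _ in group),
                )
            )

        index = index_dates.get(person_id) if index_dates else None

        def _pre(r: DetectedRegimen) -> bool:
            return index is not None and r.start_date < index

        pre = [r for r in person_regimens if _pre(r)]
        post = [r for r in person_regimens if not _pre(r)]
        for seq in (pre, post):
            for line, reg in enumerate(sorted(seq, key=lambda r: r.start_date), start=1):
                reg.line_number = line
        detected.extend(person_regimens)
    return detected


def detect_regimens(
    source: CdmStore | Iterable[DrugExposure],
    graph: ConceptGraph,
    definitions: Sequence[RegimenDefinition],
    config: DetectionConfig | None = None,
    index_dates: Mapping[int, date] | None = None,
) -> list[DetectedRegimen]:
    """Run the full detection pipeline over a store or exposure list."""
    config = config or DetectionConfig()
    exposures = (
        list(source.drug_exposures.values())
        if isinstance(source, CdmStore)
        else list(source)
    )
    norm = normalize_to_ingredients(exposures, graph, config.antineoplastic_root)
    oncologic = [
        e for e in norm.exposures if e.drug_exposure_id not in norm.non_oncologic_ids
    ]
    by_id = {e.drug_exposure_id: e for e in oncologic}
    eras = build_eras(oncologic, config.era_gap_days)
    eras_by_person: dict[int, list[IngredientEra]] = {}
    for era in eras:
        eras_by_person.setdefault(era.person_id, []).append(era)

    matched: list[tuple[Cycle, int | None]] = []
    for person_id in sorted(eras_by_person):
        for cycle in detect_cycles(
            eras_by_person[person_id], config.cycle_window_days, by_id
        ):
            matched.append(
                (
                    cycle,
                    match_regimen(
                        cycle.ingredients, definitions, config.require_exact_match
                    ),
                )
            )
    return assemble_regimens(
        matched, definitions, config.max_cycle_gap_days, index_dates
    )


def emit_episodes(
    detected: Sequence[DetectedRegimen],
    store: CdmStore,
    definitions: Sequence[RegimenDefinition],
) -> CdmStore:
    """Write detected regimens as nested Treatment Regimen / Treatment Cycle
    episodes, linking every constituent drug exposure to its cycle.

    The regimen episode's ``episode_number`` carries the line of therapy;
    each cycle episode's carries the cycle ordinal.
    """
    defs = {d.regimen_concept_id: d for d in definitions}
    for reg in sorted(detected, key=lambda r: (r.person_id, r.start_date)):
        cycle_len = defs[reg.regimen_concept_id].cycle_length_days
        regimen_ep = store.create_episode(
            person_id=reg.person_id,
            episode_concept_id=C.TREATMENT_REGIMEN,
            episode_object_concept_id=reg.regimen_concept_id,
            start_date=reg.start_date,
            end_date=reg.end_date,
            episode_number=reg.line_number or None,
        )
        for (number, start, _ingredients), exposure_ids in zip(
            reg.cycles, reg.cycle_exposure_ids
        ):
            cycle_end = min(start + timedelta(days=cycle_len - 1), reg.end_date)
            cycle_ep = store.create_episode(
                person_id=reg.person_id,
                episode_concept_id=C.TREATMENT_CYCLE,
                episode_object_concept_id=reg.regimen_concept_id,
                start_date=start,
                end_date=cycle_end,
                episode_parent_id=regimen_ep.episode_id,
                episode_number=number,
            )
            for eid in exposure_ids:
                store.link_event(cycle_ep.episode_id, eid, C.FIELD_DRUG_EXPOSURE)
    return store
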