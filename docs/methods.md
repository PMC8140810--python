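# Methods

This note records the models implemented by `oncomop`, the parameters that
matter, the design choices made where the design was genuinely open, and
what the synthetic fixtures do and do not establish.

## Vocabulary layer

Concepts, typed relationships and an explicit ancestor closure are held in
a `ConceptGraph`. The closure is exactly the transitive closure of the
`Is a` relationship plus reflexive rows; `min_levels`/`max_levels` are the
shortest and longest `Is a` path lengths, computed by dynamic programming
over a topological order (a cycle in `Is a` is a hard error reporting one
cycle). Files use the distributed vocabulary dialect — tab-delimited,
upper-case headers, `S`/empty standard flag, UTF-8, no quoting — so real
vocabulary exports can be dropped in. Validity dates, `invalid_reason` and
drug strength are out of scope; every concept is treated as currently
valid. Newly minted concepts take identifiers from a deterministic counter
starting at 2,000,000,000 (the convention for site-local concepts), in
sorted concept-code order, so repeated runs mint identical ids.

## Diagnosis precoordination and hierarchy integration

An ICD-O-3 diagnosis is `HHHH/B-Cnn.n` with histology 8000–9999, behavior
0–3, topography `Cnn[.n]`. Only *observed* triples are instantiated as
Condition concepts; the theoretical cross-product is never materialized.
The behavior digit participates through the histology axis: each `HHHH/B`
pair is a single vocabulary concept with its own morphology equivalence,
because morphology meaning depends on behavior.

Integration is two-step. Step 1 resolves the histology/behavior pair and
the topography, via `Maps to` equivalences, to a SNOMED *associated
morphology* and *finding site* attribute pair. Step 2 looks for a standard
disorder whose two attributes equal the pair **exactly**: if found, the
ICD-O concept is mapped to it and the disorder remains the standard
concept; if not, the ICD-O concept itself becomes a standard disorder,
receives the two attribute edges, and is placed under the most specific
existing disorder(s) that subsume the intersection (morphology attribute an
ancestor-or-equal of the pair's morphology AND site attribute an
ancestor-or-equal of the pair's site, with no more specific such disorder
below it). Decisions taken where the procedure was underdetermined:

- *Exactness predicate.* "Equivalence" is strict equality of both
  attribute concepts. A disorder sitting at a coarser morphology (the
  fixture's carcinoma-of-breast carries the broader *malignant epithelial
  neoplasm* morphology) therefore subsumes but does not match, which is
  what makes `8010/3-C50.9` an insertion rather than a mapping.
- *Ties.* Multiple exact equivalents resolve to the lowest concept id with
  a warning; the model assumes uniqueness.
- *Polyhierarchy.* Multiple minimal parents are allowed, matching SNOMED
  conventions; non-minimal subsumers are pruned both by attribute
  subsumption and by the disorder hierarchy itself.
- *No subsumer.* The parent defaults to a configured root (the fixture's
  "Neoplastic disease") with a warning.
- *Idempotence.* Re-integrating an already-integrated concept returns the
  prior outcome without touching the graph.

Insertion only adds hierarchy rows, so every pre-existing
ancestor/descendant pair survives — the property that keeps existing
descendant-expansion queries valid.

Cancer-type linkage is a topography-prefix rule table (e.g. `C50` → cancer
type: breast); an uncovered prefix warns and adds no edge.

## Clinical layer and episodes

Dates are whole calendar days; all intervals are closed. A modifier
measurement carries `modifier_of_event_id` and
`modifier_of_field_concept_id`, must reference an event of the same
person, and holds exactly one of a concept value or a numeric value (with
units). Episodes form a forest: a child's interval must be contained in
its parent's; an episode with no end date is ongoing and contains any
event from its start. Events link to episodes by their start date.
Column names follow the CDM convention (lower-case, comma-separated files).

Death reconciliation unions EHR and registry records by person. When both
sources disagree on the date, the earlier date wins (conservative for
survival estimation) and the person is flagged. `additional_deaths` counts
registry-only persons; `percent_increase` is `100 × additional / EHR
deaths`, defined as 0 with a warning when there are no EHR deaths.

## Regimen detection

Matching uses ingredient identity and timing only. Dosing is deliberately
excluded in this version — no principled threshold exists without
reference dosing data — and quantity is carried through for reporting.
Defaults, all configurable in `DetectionConfig`:

| parameter            | default | meaning |
|----------------------|---------|---------|
| `era_gap_days`       | 30      | max gap merging exposures into one ingredient era |
| `cycle_window_days`  | 14      | window absorbing administration starts into one cycle |
| `max_cycle_gap_days` | 90      | max inter-cycle gap within one regimen/line |
| `require_exact_match`| False   | subset matching on/off |

These follow common oncology-analytics practice; studies should vary them.
Cycle detection is greedy left-to-right over administration start dates
(the constituent exposure starts of the eras): a cycle opens at the
earliest unconsumed start and absorbs every start within the window; each
start is consumed once. Matching prefers exact ingredient-set equality,
then the largest definition fully contained in the observed set — a
definition may be a subset of the observed ingredients (co-medication
tolerance), but observed ingredients may not cover only part of a
definition (a missing component means no match). Both behaviors sit behind
`require_exact_match` because field practice varies. Exposures whose
ingredient does not descend from the antineoplastic class are excluded
from matching but passed through flagged.

Lines of therapy number each person's detected regimens in start order; a
new line opens when the regimen concept changes or the inter-cycle gap is
exceeded. When an index diagnosis date is supplied, numbering restarts at
the first regimen on/after it (pre-index regimens are numbered in their
own sequence). Emitted regimen episodes carry the line number in
`episode_number`; cycle episodes carry the cycle ordinal and link every
constituent exposure through `EPISODE_EVENT`.

## Tumor-registry ETL

The transformation is driven by item-mapping rules held as data. Required
items are primary site (400), histology (522), behavior (523) and date of
diagnosis (390); a record missing any is rejected with a reason. The
combined code is assembled as `histology/behavior-site` (the site's dot,
elided in registry convention, is restored), looked up among
precoordinated concepts, and followed to its designated standard concept.
Unknown or non-integrated codes count as *unmapped* and drive the coverage
metric `mapped / (mapped + unmapped)`; rejected records are excluded from
the denominator. Dates are `YYYYMMDD`; a year-only date resolves to July 1
and is flagged. Vital-status items yield registry death records dated by
last contact, reconciled against EHR deaths downstream. Run reports
satisfy the conservation identity `records_in = mapped + unmapped +
rejected`. The rule schema (categorical value maps, numeric items with
units, vital status) is this package's formalization of a
vocabulary-driven ETL; real registry fixed-width/XML dialects are out of
scope behind the reader adapter.

## Characterization

Cohort entry requires a condition in the index concept set expanded
through the hierarchy, optionally a modifier measurement (concept + value)
linked to a qualifying condition, and optionally a regimen episode on or
after the index date (earliest qualifying diagnosis). The observation
window ends at the last recorded event or a fixed cutoff, whichever is
first. First-line is the earliest regimen episode on/after index; members
without one count as "Untreated" when therapy is not required. Category
grouping is total via an explicit "Other" fallback. Age at index is index
year minus birth year (years are all the person table holds); medians use
the midpoint-of-two-central-order-statistics convention; first-line
duration is the closed-interval length in days.

## Synthetic fixtures and what the tests show

The fixture vocabulary encodes the breast-cancer subtree used by the
worked examples, with the published identifiers for breast structure,
carcinoma morphology and the two disorders, and locally minted ids
(2,000,000,0xx) for everything not published. Its one deliberate modelling
choice — carcinoma-of-breast carrying the coarser morphology — realizes
the documented integration outcomes under the strict-equality predicate.

`simulate_patients` plants, per person: a diagnosis triple with date, one
or two regimens drawn from a frequency catalog (default 45% paclitaxel +
bevacizumab, 35% gemcitabine + cisplatin, 20% gemcitabine monotherapy),
2–6 cycles at the definition's cycle length with optional ±jitter,
component exposures on consecutive days within the cycle, optional
supportive-care co-medication at a configurable rate, EHR deaths (25%),
registry-only deaths (8%), registry abstracts for a covered fraction
(90%), and a 60% metastatic fraction. Defaults describe a noise-free
cohort of 200; jitter and co-medication are switched on explicitly when
robustness is under study. Inter-regimen gaps are drawn from 100–150 days
so that a repeat of the same regimen is always a new line. A single seeded
generator stream makes every output byte-reproducible; the seed is
recorded in the output manifest.

The generator emulates the *timing structure* of chemotherapy records and
the item structure of registry abstracts. It does not emulate dose
variation, partial or abandoned cycles, ingredient substitutions within a
regimen, overlapping regimens, registry coding errors, or realistic
marginal distributions of demographics and survival. Perfect recovery on
noise-free simulations therefore validates the algorithmic contract, not
field accuracy; the jitter/co-medication condition probes robustness only
along those two axes.

Problem sizes were chosen to keep the full suite fast at desk scale:
simulations of 150–250 persons, random-graph oracles up to 200 nodes × 100
replicates, attribute-world oracles up to 50 disorders. The acceptance
script runs the integration worked examples on the 36-concept fixture
vocabulary.

## Known limitations

- No OWL/description-logic classification; hierarchy placement relies on
  the attribute-subsumption heuristic above.
- Concept lifecycle (deprecation, remapping) is not modeled.
- Radiotherapy and surgical treatment episodes, and probabilistic episode
  derivation, are out of scope.
- The modifier concept set covers only the handful of modifiers the
  fixtures need; authoring a complete modifier ontology is a separate
  terminology effort.
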