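# oncomop

An oncology extension toolkit for OMOP-style observational research data.
It addresses a gap that makes cancer studies hard on a general-purpose
common data model (CDM): cancer diagnoses are defined by histology,
behavior and anatomic site together; treatments come as multi-drug regimens
delivered in cycles; and the clinically meaningful units of analysis are
*episodes* (first occurrence, progression, regimen, cycle) rather than
individual coded events.

`oncomop` is a library for data engineers and informaticists who harmonize
EHR and tumor-registry data for observational cancer research. It provides:

- **Vocabulary store** (`vocab_store`) — concepts, typed relationships and a
  derived ancestor closure, read/written in the standard tab-delimited
  vocabulary dialect (`CONCEPT.csv`, `CONCEPT_RELATIONSHIP.csv`,
  `CONCEPT_ANCESTOR.csv`).
- **ICD-O-3 integration** (`icdo_integration`) — precoordinates observed
  (histology, behavior, topography) triples such as `8520/3-C50.9` into
  single Condition concepts and integrates each into a SNOMED-style disease
  hierarchy in two steps: (1) resolve the ICD-O axes to SNOMED *associated
  morphology* and *finding site* attributes; (2) map to the disorder at the
  exact attribute intersection if one exists, otherwise insert the new
  concept as a standard disorder under the most specific subsuming
  disorder(s). Insertion never removes hierarchy pairs, so existing
  descendant-expanding queries keep working.
- **CDM core** (`cdm_core`) — persons, condition occurrences, modifier
  measurements with explicit diagnosis linkage, drug exposures, nested
  `EPISODE`/`EPISODE_EVENT` tables, and EHR/registry death reconciliation
  (`merge_vital_status`).
- **Regimen detection** (`regimen_detection`) — a rule-based algorithm that
  normalizes exposures to ingredients, builds ingredient eras, groups
  administrations into cycles, matches cycles against regimen definitions
  (ingredient set + cycle length), and assembles nested regimen/cycle
  episodes with lines of therapy.
- **Tumor-registry ETL** (`naaccr_etl`) — a vocabulary-driven transformation
  of item-number-keyed registry abstracts into conditions, linked modifier
  measurements, disease episodes and registry death records, with a
  diagnosis-coverage report.
- **Characterization** (`characterization`) — cohort identification with
  hierarchy expansion and modifier/therapy requirements, and first-line
  regimen distributions with category grouping.
- **Synthetic fixtures** (`synthetic_fixtures`) — seeded generators for the
  breast-cancer vocabulary subtree and for cohorts with planted regimen
  histories, registry abstracts and deaths, including the ground truth
  needed to score recovery.

## Worked example

`python examples/integrate_diagnoses.py` integrates the two observed
breast-cancer diagnoses against the fixture vocabulary:

```
   icdo_code       mode  standard_concept_id   parents
8010/3-C50.9   INSERTED           2000000000 254838004
8520/3-C50.9 EQUIVALENT            278054005

8010/3-C50.9 sits at the intersection of finding site 76752008 (breast
structure) and morphology 68453008 (carcinoma).
descendants of carcinoma of breast now: [254838004, 278054005, 2000000000]
```

`8520/3-C50.9` (lobular carcinoma, NOS, of breast, NOS) has an exact
attribute equivalent, so it is mapped to SNOMED concept 278054005
(infiltrating lobular carcinoma of breast), which stays the standard
concept. `8010/3-C50.9` (carcinoma, NOS, of breast, NOS) has no exact
equivalent, so a new standard concept (id 2000000000, minted in the local
2-billion range) is inserted as a child of 254838004 (carcinoma of breast);
the descendant list shows the hierarchy gained the new concept without
losing the old one.

The other examples exercise the rest of the toolkit end to end —
`detect_regimens.py` (episode derivation from drug exposures),
`registry_etl.py` (registry conversion and death reconciliation, e.g.
`EHR deaths: 29; registry added 8 (27.6% increase in death count)`), and
`characterize_cohort.py` (a metastatic breast-cancer cohort and its
first-line regimen distribution).

A thin command-line surface mirrors the library:
`oncomop fixtures vocab|simulate`, `oncomop vocab validate|rebuild-ancestors`,
`oncomop integrate`, `oncomop cdm validate`, `oncomop detect-regimens`,
`oncomop etl-naaccr`, `oncomop characterize`.

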