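"""End-to-end: simulate, ETL, regimen detection, then characterize the
first-line treatment of a metastatic breast-cancer cohort.

The cohort is defined by the carcinoma-of-breast concept expanded through
the hierarchy (so both the pre-existing SNOMED disorder and the newly
inserted ICD-O concept qualify), a metastatic-status modifier requirement,
and at least one systemic-therapy regimen after diagnosis.
"""

from oncomop import (
    CohortDefinition,
    SimulationConfig,
    TreatmentCategoryMap,
    detect_regimens,
    emit_episodes,
    first_line_distribution,
    identify_cohort,
    integrate_all,
    make_fixture_vocab,
    precoordinate,
    run_etl,
    simulate_patients,
)
from oncomop import concepts as C
from oncomop.synthetic_fixtures import (
    DIAGNOSIS_CATALOG,
    default_mapping_rules,
    default_regimen_definitions,
)

graph = make_fixture_vocab()
precoordinate([code for code, *_ in DIAGNOSIS_CATALOG], graph)
integrate_all(graph)

result = simulate_patients(SimulationConfig(n_persons=200, seed=7))
store = result.store
store.graph = graph
run_etl(result.registry_records, default_mapping_rules(), graph, store)

definitions = default_regimen_definitions()
detected = detect_regimens(store, graph, definitions)
emit_episodes(detected, store, definitions)

cohort = identify_cohort(
    CohortDefinition(
        index_condition_concept_ids={C.CARCINOMA_OF_BREAST},
        required_modifier=(C.METASTASIS_STATUS, C.METASTATIC),
        require_systemic_therapy=True,
    ),
    store,
    graph,
)
categories = TreatmentCategoryMap(
    {
        C.REGIMEN_PACLITAXEL_BEVACIZUMAB: "Taxane + targeted",
        C.REGIMEN_GEMCITABINE_CISPLATIN: "Platinum combination",
        C.REGIMEN_GEMCITABINE_MONO: "Single agent",
    }
)
table, summaries = first_line_distribution(cohort, store, categories)
print(f"cohort size: {len(cohort)}")
print(table.to_string(index=False))
print(summaries)
# percents sum to 100 over the treatment categories of each member's
# first-line regimen; the summaries give median age at index, percent male
# and median first-line duration in days.
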