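"""Precoordinate two observed ICD-O-3 breast-cancer diagnoses and integrate
them into the SNOMED-style hierarchy.

8520/3-C50.9 (lobular carcinoma NOS of breast NOS) has an exact attribute
equivalent and is mapped to it; 8010/3-C50.9 (carcinoma NOS of breast NOS)
has none and is inserted as a new standard child of carcinoma of breast.
"""

from oncomop import (
    integrate_all,
    integration_report,
    link_cancer_type,
    make_fixture_vocab,
    precoordinate,
    resolve_attributes,
)
from oncomop import concepts as C

graph = make_fixture_vocab()
codes = ["8520/3-C50.9", "8010/3-C50.9"]
precoordinate(codes, graph)
outcomes = integrate_all(graph, codes, type_rules={"C50": C.CANCER_TYPE_BREAST})

print(integration_report(outcomes, graph).to_string(index=False))
pair = resolve_attributes("8010/3-C50.9", graph)
print(
    f"\n8010/3-C50.9 sits at the intersection of finding site "
    f"{pair.finding_site_concept_id} (breast structure) and morphology "
    f"{pair.morphology_concept_id} (carcinoma)."
)
print(
    "descendants of carcinoma of breast now:",
    sorted(graph.descendants_of(C.CARCINOMA_OF_BREAST)),
)
# EQUIVALENT rows keep the SNOMED disorder as the standard concept; the
# INSERTED row becomes standard itself, preserving all pre-existing
# hierarchy pairs so old cohort queries still work.
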