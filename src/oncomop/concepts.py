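"""Well-known concept identifiers used across the toolkit.

The five SNOMED CT identifiers (breast structure, carcinoma morphology, the
two breast-carcinoma disorders, and the infiltrating lobular carcinoma
disorder) are the published identifiers for the breast-cancer worked
examples.  Everything else is a locally minted concept and lives in the
2,000,000,000+ range, the OMOP convention for site-local concepts.
"""

# SNOMED CT concepts with published identifiers
BREAST_STRUCTURE = 76752008  # body structure
CARCINOMA_MORPHOLOGY = 68453008  # morphologic abnormality
CARCINOMA_OF_BREAST = 254838004  # disorder
INFILTRATING_LOBULAR_CARCINOMA_OF_BREAST = 278054005  # disorder

# Locally minted SNOMED-style concepts (ids not published; 2e9 range)
LOBULAR_CARCINOMA_MORPHOLOGY = 2000000001
NEOPLASTIC_DISEASE = 2000000002  # fallback hierarchy root for insertions
CANCER_TYPE_BREAST = 2000000003
MALIGNANT_EPITHELIAL_NEOPLASM_MORPHOLOGY = 2000000005

# Episode-domain concepts (disease / treatment abstractions)
DISEASE_FIRST_OCCURRENCE = 2000000011
DISEASE_PROGRESSION = 2000000012
TREATMENT_REGIMEN = 2000000013
TREATMENT_CYCLE = 2000000014

# ICD-O-3 component concepts (histology/behavior pairs and topography)
ICDO_HISTOLOGY_8520_3 = 2000000021
ICDO_HISTOLOGY_8010_3 = 2000000022
ICDO_TOPOGRAPHY_C50_9 = 2000000023

# Drug classification and RxNorm-style ingredients
ANTINEOPLASTIC_AGENT = 2000000030
PACLITAXEL = 2000000031
BEVACIZUMAB = 2000000032
GEMCITABINE = 2000000033
CISPLATIN = 2000000034
DEXAMETHASONE = 2000000035  # supportive care, not antineoplastic
ONDANSETRON = 2000000036  # supportive care, not antineoplastic
PACLITAXEL_INJECTION = 2000000037  # branded/clinical drug mapping to paclitaxel

# HemOnc-style regimen concepts
REGIMEN_PACLITAXEL_BEVACIZUMAB = 2000000041
REGIMEN_GEMCITABINE_CISPLATIN = 2000000042
REGIMEN_GEMCITABINE_MONO = 2000000043

# Diagnostic-modifier measurement concepts and values
METASTASIS_STATUS = 2000000051
METASTATIC = 2000000052
NOT_METASTATIC = 2000000053
ER_STATUS = 2000000054
ER_POSITIVE = 2000000055
ER_NEGATIVE = 2000000056
TUMOR_SIZE = 2000000057

# Metadata concepts naming CDM tables (modifier / episode-event linkage)
FIELD_CONDITION_OCCURRENCE = 2000000061
FIELD_DRUG_EXPOSURE = 2000000062
FIELD_EPISODE = 2000000063

# OMOP gender concepts (conventional ids)
GENDER_MALE = 8507
GENDER_FEMALE = 8532
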