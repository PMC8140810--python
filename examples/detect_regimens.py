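"""Derive treatment-regimen and cycle episodes from raw drug exposures.

Simulates 20 patients with planted chemotherapy histories, runs the
rule-based detection (ingredient normalization -> eras -> cycles -> regimen
matching -> line assembly) and prints the recovered regimens.
"""

from oncomop import (
    DetectionConfig,
    SimulationConfig,
    detect_regimens,
    emit_episodes,
    make_fixture_vocab,
    simulate_patients,
)
from oncomop.synthetic_fixtures import default_regimen_definitions

graph = make_fixture_vocab()
definitions = default_regimen_definitions()
result = simulate_patients(SimulationConfig(n_persons=20, seed=42))

detected = detect_regimens(result.store, graph, definitions, DetectionConfig())
emit_episodes(detected, result.store, definitions)

names = {d.regimen_concept_id: d.name for d in definitions}
for reg in detected[:8]:
    print(
        f"person {reg.person_id:>3}  line {reg.line_number}  "
        f"{names[reg.regimen_concept_id]:<28} {len(reg.cycles)} cycles  "
        f"{reg.start_date} .. {reg.end_date}"
    )
print(f"...\ndetected {len(detected)} regimens, planted {len(result.planted_regimens)}")
print(
    f"episode rows written: {len(result.store.episodes)} "
    f"(regimens + nested cycles), episode_event links: "
    f"{len(result.store.episode_events)}"
)
# Each detected regimen becomes a Treatment Regimen episode whose
# episode_number is the line of therapy; its cycles nest beneath it and
# every contributing drug exposure is linked through EPISODE_EVENT.
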