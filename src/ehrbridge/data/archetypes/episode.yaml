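# Entry-level archetype "episode": one emergency-room or hospitalization
# episode. Element list reconstructed from the Visit_occurrence correspondence.
archetype_id: EHRB-ENTRY.episode.v1
version: "1"
language: en
description: >-
  One care episode (emergency room attendance or hospitalization) with its
  admission and discharge moments and discharge disposition.
entry:
  name: Episode
  elements:
    - node_id: episode_id
      name: Episode ID
      kind: IDENTIFIER
      mandatory: true
    - node_id: patient_id
      name: Patient ID
      kind: IDENTIFIER
      mandatory: true
    - node_id: episode_type
      name: Episode type
      kind: CODED_TEXT
      mandatory: true
      terminology_binding: local
    - node_id: admission_datetime
      name: Admission date and time
      kind: DATE_TIME
      mandatory: true
    - node_id: discharge_datetime
      name: Discharge date and time
      kind: DATE_TIME
      mandatory: false
    - node_id: discharge_type
      name: Discharge disposition
      kind: CODED_TEXT
      mandatory: false
      terminology_binding: local
    - node_id: source
      name: Source system
      kind: SIMPLE_TEXT
      mandatory: true
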