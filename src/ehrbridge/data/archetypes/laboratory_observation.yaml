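# Entry-level archetype "laboratory observation": one laboratory result.
# Element list reconstructed from the Measurement-table correspondence.
archetype_id: EHRB-ENTRY.laboratory_observation.v1
version: "1"
language: en
description: >-
  One laboratory result with a LOINC-coded analyte and a numeric value
  with units.
entry:
  name: LaboratoryObservation
  elements:
    - node_id: lab_observation_id
      name: Laboratory observation ID
      kind: IDENTIFIER
      mandatory: true
    - node_id: patient_id
      name: Patient ID
      kind: IDENTIFIER
      mandatory: true
    - node_id: episode_id
      name: Episode ID
      kind: IDENTIFIER
      mandatory: true
    - node_id: analyte
      name: Analyte
      kind: CODED_TEXT
      mandatory: true
      terminology_binding: LOINC
    - node_id: observation_datetime
      name: Result date and time
      kind: DATE_TIME
      mandatory: true
    - node_id: value
      name: Result value
      kind: QUANTITY
      mandatory: true
    - node_id: source
      name: Source system
      kind: SIMPLE_TEXT
      mandatory: true
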