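# Entry-level archetype "clinical observation": one bedside measurement
# (vital signs and similar). Element list reconstructed from the
# Measurement-table correspondence.
archetype_id: EHRB-ENTRY.clinical_observation.v1
version: "1"
language: en
description: >-
  One clinical (bedside) observation with a LOINC-coded concept and a
  numeric value with units.
entry:
  name: ClinicalObservation
  elements:
    - node_id: observation_id
      name: Observation ID
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
    - node_id: observation
      name: Observed concept
      kind: CODED_TEXT
      mandatory: true
      terminology_binding: LOINC
    - node_id: observation_datetime
      name: Observation date and time
      kind: DATE_TIME
      mandatory: true
    - node_id: value
      name: Observed value
      kind: QUANTITY
      mandatory: true
    - node_id: source
      name: Source system
      kind: SIMPLE_TEXT
      mandatory: true
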