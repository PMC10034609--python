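# Entry-level archetype "diagnosis": one coded diagnosis recorded in an
# episode of care. The six elements and their order are the documented ones.
archetype_id: EHRB-ENTRY.diagnosis.v1
version: "1"
language: en
description: >-
  A single diagnosis recorded during a care episode, coded against
  ICD-10-CM, with the date and time of record and its episode context.
entry:
  name: Diagnosis
  elements:
    - node_id: episode_id
      name: Episode ID
      kind: IDENTIFIER
      mandatory: true
    - node_id: diagnosis
      name: Diagnosis
      kind: CODED_TEXT
      mandatory: true
      terminology_binding: ICD-10-CM
    - node_id: diagnosis_datetime
      name: Date and time of record
      kind: DATE_TIME
      mandatory: true
    - node_id: patient_id
      name: Patient ID
      kind: IDENTIFIER
      mandatory: true
    - node_id: diagnosis_id
      name: Diagnosis ID
      kind: IDENTIFIER
      mandatory: true
    - node_id: source
      name: Source system
      kind: SIMPLE_TEXT
      mandatory: true
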