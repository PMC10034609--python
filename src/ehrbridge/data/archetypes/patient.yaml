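# Entry-level archetype "patient": demographic identity of one subject of
# care. Element list reconstructed from the Person-table correspondence.
archetype_id: EHRB-ENTRY.patient.v1
version: "1"
language: en
description: Demographic record of a subject of care.
entry:
  name: Patient
  elements:
    - node_id: patient_id
      name: Patient ID
      kind: IDENTIFIER
      mandatory: true
    - node_id: birth_date
      name: Date of birth
      kind: DATE_TIME
      mandatory: true
    - node_id: sex
      name: Administrative sex
      kind: CODED_TEXT
      mandatory: true
      terminology_binding: local
    - node_id: source
      name: Source system
      kind: SIMPLE_TEXT
      mandatory: true
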