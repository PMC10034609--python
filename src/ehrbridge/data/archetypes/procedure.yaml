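# Entry-level archetype "procedure": one performed procedure. The boolean
# device flag marks procedures that expose a medical device; flagged rows
# feed the device-exposure derivation. Reconstructed element list.
archetype_id: EHRB-ENTRY.procedure.v1
version: "1"
language: en
description: >-
  One procedure performed on a patient during an episode, coded against
  SNOMED CT, with a flag for device-exposing procedures.
entry:
  name: Procedure
  elements:
    - node_id: procedure_id
      name: Procedure ID
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
    - node_id: procedure
      name: Procedure
      kind: CODED_TEXT
      mandatory: true
      terminology_binding: SNOMED CT
    - node_id: procedure_datetime
      name: Procedure date and time
      kind: DATE_TIME
      mandatory: true
    - node_id: is_device
      name: Device-exposing procedure
      kind: BOOLEAN
      mandatory: false
    - node_id: source
      name: Source system
      kind: SIMPLE_TEXT
      mandatory: true
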