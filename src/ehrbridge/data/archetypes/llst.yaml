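# Entry-level archetype "limitation of life-sustaining treatment": one
# recorded care-limitation decision. Reconstructed element list.
archetype_id: EHRB-ENTRY.llst.v1
version: "1"
language: en
description: >-
  A recorded decision to limit life-sustaining treatment for a patient,
  coded against SNOMED CT.
entry:
  name: LimitationOfLifeSustainingTreatment
  elements:
    - node_id: llst_id
      name: Limitation record ID
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
    - node_id: llst
      name: Limitation of life-sustaining treatment
      kind: CODED_TEXT
      mandatory: true
      terminology_binding: SNOMED CT
    - node_id: llst_datetime
      name: Decision date and time
      kind: DATE_TIME
      mandatory: true
    - node_id: source
      name: Source system
      kind: SIMPLE_TEXT
      mandatory: true
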