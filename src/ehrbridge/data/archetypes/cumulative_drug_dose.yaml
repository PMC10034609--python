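# Entry-level archetype "cumulative drug dose": total dose of one drug
# accumulated over a period within an episode. Reconstructed element list.
archetype_id: EHRB-ENTRY.cumulative_drug_dose.v1
version: "1"
language: en
description: >-
  Cumulative dose of one drug received by a patient over a stated period of
  an episode.
entry:
  name: CumulativeDrugDose
  elements:
    - node_id: cumulative_dose_id
      name: Cumulative dose ID
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
    - node_id: drug
      name: Drug
      kind: CODED_TEXT
      mandatory: true
      terminology_binding: SNOMED CT
    - node_id: period_start
      name: Accumulation period start
      kind: DATE_TIME
      mandatory: true
    - node_id: period_end
      name: Accumulation period end
      kind: DATE_TIME
      mandatory: true
    - node_id: cumulative_dose
      name: Cumulative dose
      kind: QUANTITY
      mandatory: true
    - node_id: source
      name: Source system
      kind: SIMPLE_TEXT
      mandatory: true
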