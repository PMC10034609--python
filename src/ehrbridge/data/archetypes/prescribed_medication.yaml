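# Entry-level archetype "prescribed medication": one drug prescription
# order. Element list reconstructed from the Drug_exposure correspondence.
archetype_id: EHRB-ENTRY.prescribed_medication.v1
version: "1"
language: en
description: One drug prescription issued to a patient during an episode.
entry:
  name: PrescribedMedication
  elements:
    - node_id: prescription_id
      name: Prescription ID
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
    - node_id: prescription_datetime
      name: Prescription date and time
      kind: DATE_TIME
      mandatory: true
    - node_id: dose
      name: Prescribed dose
      kind: QUANTITY
      mandatory: true
    - node_id: frequency
      name: Dosing frequency
      kind: SIMPLE_TEXT
      mandatory: false
    - node_id: source
      name: Source system
      kind: SIMPLE_TEXT
      mandatory: true
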