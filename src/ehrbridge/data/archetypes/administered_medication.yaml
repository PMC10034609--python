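# Entry-level archetype "administered medication": one drug administration
# act. Element list reconstructed from the Drug_exposure correspondence.
archetype_id: EHRB-ENTRY.administered_medication.v1
version: "1"
language: en
description: One administration of a drug to a patient during an episode.
entry:
  name: AdministeredMedication
  elements:
    - node_id: administration_id
      name: Administration ID
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
    - node_id: administration_datetime
      name: Administration date and time
      kind: DATE_TIME
      mandatory: true
    - node_id: dose
      name: Administered dose
      kind: QUANTITY
      mandatory: true
    - node_id: route
      name: Route of administration
      kind: SIMPLE_TEXT
      mandatory: false
    - node_id: source
      name: Source system
      kind: SIMPLE_TEXT
      mandatory: true
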