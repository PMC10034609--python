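# Entry-level archetype "health problem": a problem-list item. Included to
# complete the twelve-concept library; no extract pipeline feeds it here
# because its source is free text processed outside this package.
archetype_id: EHRB-ENTRY.health_problem.v1
version: "1"
language: en
description: >-
  One health problem of a patient, coded against SNOMED CT. Library member
  only; not wired to a tabular extract pipeline.
entry:
  name: HealthProblem
  elements:
    - node_id: problem_id
      name: Problem ID
      kind: IDENTIFIER
      mandatory: true
    - node_id: patient_id
      name: Patient ID
      kind: IDENTIFIER
      mandatory: true
    - node_id: problem
      name: Health problem
      kind: CODED_TEXT
      mandatory: true
      terminology_binding: SNOMED CT
    - node_id: onset_datetime
      name: Onset date and time
      kind: DATE_TIME
      mandatory: false
    - node_id: source
      name: Source system
      kind: SIMPLE_TEXT
      mandatory: true
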