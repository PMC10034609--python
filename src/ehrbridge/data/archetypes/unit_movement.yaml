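# Entry-level archetype "movements between units": one stay of a patient in
# a hospital unit within an episode. The level-of-care element is assigned
# by categorizing the unit code. Reconstructed element list.
archetype_id: EHRB-ENTRY.unit_movement.v1
version: "1"
language: en
description: >-
  One movement of a patient into a hospital unit during an episode, with
  the unit's level of care.
entry:
  name: UnitMovement
  elements:
    - node_id: movement_id
      name: Movement ID
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
    - node_id: unit
      name: Hospital unit
      kind: CODED_TEXT
      mandatory: true
      terminology_binding: local
    - node_id: level_of_care
      name: Level of care
      kind: SIMPLE_TEXT
      mandatory: false
    - node_id: start_datetime
      name: Unit entry date and time
      kind: DATE_TIME
      mandatory: true
    - node_id: end_datetime
      name: Unit exit date and time
      kind: DATE_TIME
      mandatory: false
    - node_id: source
      name: Source system
      kind: SIMPLE_TEXT
      mandatory: true
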