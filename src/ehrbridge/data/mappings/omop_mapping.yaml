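# Archetype ↔ OMOP CDM correspondence: one row per archetype, element →
# CDM column target(s). The three medication archetypes all feed
# Drug_exposure; clinical and laboratory observations both feed Measurement;
# the limitation-of-life-sustaining-treatment concept feeds Observation.
# The health-problem archetype has no row (no tabular pipeline feeds it).
- archetype_id: EHRB-ENTRY.patient.v1
  omop_table: Person
  elements:
    patient_id:
      - {column: person_id}
      - {column: person_source_value}
    birth_date: birth_datetime
    sex: gender_source_value

- archetype_id: EHRB-ENTRY.episode.v1
  omop_table: Visit_occurrence
  elements:
    episode_id: visit_occurrence_id
    patient_id: person_id
    episode_type: visit_source_value
    admission_datetime: visit_start_datetime
    discharge_datetime: visit_end_datetime
    discharge_type: discharged_to_source_value

- archetype_id: EHRB-ENTRY.diagnosis.v1
  omop_table: Condition_occurrence
  elements:
    diagnosis_id: condition_occurrence_id
    patient_id: person_id
    episode_id: visit_occurrence_id
    diagnosis: condition_source_value
    diagnosis_datetime: condition_start_datetime

- archetype_id: EHRB-ENTRY.administered_medication.v1
  omop_table: Drug_exposure
  elements:
    administration_id: drug_exposure_id
    patient_id: person_id
    episode_id: visit_occurrence_id
    drug: drug_source_value
    administration_datetime: drug_exposure_start_datetime
    dose:
      - {column: quantity}
      - {column: dose_unit_source_value, part: units}
    route: route_source_value

- archetype_id: EHRB-ENTRY.prescribed_medication.v1
  omop_table: Drug_exposure
  elements:
    prescription_id: drug_exposure_id
    patient_id: person_id
    episode_id: visit_occurrence_id
    drug: drug_source_value
    prescription_datetime: drug_exposure_start_datetime
    dose:
      - {column: quantity}
      - {column: dose_unit_source_value, part: units}
    frequency: sig

- archetype_id: EHRB-ENTRY.cumulative_drug_dose.v1
  omop_table: Drug_exposure
  elements:
    cumulative_dose_id: drug_exposure_id
    patient_id: person_id
    episode_id: visit_occurrence_id
    drug: drug_source_value
    period_start: drug_exposure_start_datetime
    period_end: drug_exposure_end_datetime
    cumulative_dose:
      - {column: quantity}
      - {column: dose_unit_source_value, part: units}

- archetype_id: EHRB-ENTRY.unit_movement.v1
  omop_table: Visit_detail
  elements:
    movement_id: visit_detail_id
    patient_id: person_id
    episode_id: visit_occurrence_id
    unit: visit_detail_source_value
    start_datetime: visit_detail_start_datetime
    end_datetime: visit_detail_end_datetime

- archetype_id: EHRB-ENTRY.clinical_observation.v1
  omop_table: Measurement
  elements:
    observation_id: measurement_id
    patient_id: person_id
    episode_id: visit_occurrence_id
    observation: measurement_source_value
    observation_datetime: measurement_datetime
    value:
      - {column: value_as_number}
      - {column: unit_source_value, part: units}

- archetype_id: EHRB-ENTRY.laboratory_observation.v1
  omop_table: Measurement
  elements:
    lab_observation_id: measurement_id
    patient_id: person_id
    episode_id: visit_occurrence_id
    analyte: measurement_source_value
    observation_datetime: measurement_datetime
    value:
      - {column: value_as_number}
      - {column: unit_source_value, part: units}

- archetype_id: EHRB-ENTRY.llst.v1
  omop_table: Observation
  elements:
    llst_id: observation_id
    patient_id: person_id
    episode_id: visit_occurrence_id
    llst: observation_source_value
    llst_datetime: observation_datetime

- archetype_id: EHRB-ENTRY.procedure.v1
  omop_table: Procedure_occurrence
  elements:
    procedure_id: procedure_occurrence_id
    patient_id: person_id
    episode_id: visit_occurrence_id
    procedure: procedure_source_value
    procedure_datetime: procedure_datetime
    # carrier for the device-exposure routing flag; cleared in the post-pass
    is_device: modifier_source_value
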