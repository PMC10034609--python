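archetype_id: EHRB-ENTRY.laboratory_observation.v1
source_table: lab_observations
elements:
  lab_observation_id: {column: lab_observation_id}
  patient_id: {column: patient_id}
  episode_id: {column: episode_id}
  analyte: {column: local_test_code, transform: bind_code, local_system: HIS-LAB}
  observation_datetime: {column: observed_datetime, transform: datetime_parse}
  value: {column: value, units_column: unit}
  source: {column: source}
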