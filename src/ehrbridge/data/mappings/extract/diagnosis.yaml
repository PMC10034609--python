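archetype_id: EHRB-ENTRY.diagnosis.v1
source_table: diagnoses
elements:
  episode_id: {column: episode_id}
  diagnosis: {column: local_dx_code, transform: bind_code, local_system: HIS-DX}
  diagnosis_datetime: {column: recorded_datetime, transform: datetime_parse}
  patient_id: {column: patient_id}
  diagnosis_id: {column: diagnosis_id}
  source: {column: source}
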