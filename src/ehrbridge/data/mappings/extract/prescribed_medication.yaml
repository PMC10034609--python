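archetype_id: EHRB-ENTRY.prescribed_medication.v1
source_table: prescriptions
elements:
  prescription_id: {column: prescription_id}
  patient_id: {column: patient_id}
  episode_id: {column: episode_id}
  drug: {column: local_drug_code, transform: bind_code, local_system: HIS-DRUG}
  prescription_datetime: {column: prescribed_datetime, transform: datetime_parse}
  dose: {column: dose_value, units_column: dose_unit}
  frequency: {column: frequency}
  source: {column: source}
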