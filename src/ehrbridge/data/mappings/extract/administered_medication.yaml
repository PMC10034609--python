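archetype_id: EHRB-ENTRY.administered_medication.v1
source_table: administrations
elements:
  administration_id: {column: administration_id}
  patient_id: {column: patient_id}
  episode_id: {column: episode_id}
  drug: {column: local_drug_code, transform: bind_code, local_system: HIS-DRUG}
  administration_datetime: {column: administered_datetime, transform: datetime_parse}
  dose: {column: dose_value, units_column: dose_unit}
  route: {column: route}
  source: {column: source}
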