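archetype_id: EHRB-ENTRY.cumulative_drug_dose.v1
source_table: cumulative_doses
elements:
  cumulative_dose_id: {column: cumulative_dose_id}
  patient_id: {column: patient_id}
  episode_id: {column: episode_id}
  drug: {column: local_drug_code, transform: bind_code, local_system: HIS-DRUG}
  period_start: {column: period_start, transform: datetime_parse}
  period_end: {column: period_end, transform: datetime_parse}
  cumulative_dose: {column: total_dose_value, units_column: dose_unit}
  source: {column: source}
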