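archetype_id: EHRB-ENTRY.unit_movement.v1
source_table: movements
elements:
  movement_id: {column: movement_id}
  patient_id: {column: patient_id}
  episode_id: {column: episode_id}
  unit: {column: unit_code}
  level_of_care: {column: unit_code, transform: categorize, dimension: level_of_care}
  start_datetime: {column: start_datetime, transform: datetime_parse}
  end_datetime: {column: end_datetime, transform: datetime_parse}
  source: {column: source}
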