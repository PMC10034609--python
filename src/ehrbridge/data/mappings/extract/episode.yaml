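archetype_id: EHRB-ENTRY.episode.v1
source_table: episodes
elements:
  episode_id: {column: episode_id}
  patient_id: {column: patient_id}
  episode_type: {column: episode_type}
  admission_datetime: {column: admission_datetime, transform: datetime_parse}
  discharge_datetime: {column: discharge_datetime, transform: datetime_parse}
  discharge_type: {column: discharge_type}
  source: {column: source}
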