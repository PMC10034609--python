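archetype_id: EHRB-ENTRY.llst.v1
source_table: llst
elements:
  llst_id: {column: llst_id}
  patient_id: {column: patient_id}
  episode_id: {column: episode_id}
  llst: {column: local_llst_code, transform: bind_code, local_system: HIS-LLST}
  llst_datetime: {column: recorded_datetime, transform: datetime_parse}
  source: {column: source}
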