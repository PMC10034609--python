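archetype_id: EHRB-ENTRY.procedure.v1
source_table: procedures
elements:
  procedure_id: {column: procedure_id}
  patient_id: {column: patient_id}
  episode_id: {column: episode_id}
  procedure: {column: local_procedure_code, transform: bind_code, local_system: HIS-PROC}
  procedure_datetime: {column: procedure_datetime, transform: datetime_parse}
  is_device: {column: device_flag}
  source: {column: source}
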