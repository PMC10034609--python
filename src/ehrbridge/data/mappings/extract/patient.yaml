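archetype_id: EHRB-ENTRY.patient.v1
source_table: patients
elements:
  patient_id: {column: patient_id}
  birth_date: {column: birth_date, transform: datetime_parse}
  sex: {column: sex}
  source: {column: source}
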