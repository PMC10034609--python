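source_value,dimension,category
UNIT01,level_of_care,emergency
UNIT02,level_of_care,ward
UNIT03,level_of_care,ward
UNIT04,level_of_care,ward
UNIT05,level_of_care,intermediate_care
UNIT06,level_of_care,intensive_care
UNIT07,level_of_care,intensive_care
UNIT08,level_of_care,ward
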