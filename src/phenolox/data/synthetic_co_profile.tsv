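# synthetic catechol-oxidase anchor profile (1-based positions)
reference	CO_REF_SYN
domain	1	120
domain	121	220
domain	221	330
HisA1	20
HisA2	24
HisA3	45
gatekeeper	50
HisB1	80
HB1plus1	81
HisB2	84
HB2plus1	85
HisB3	95
waterkeeper	100
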