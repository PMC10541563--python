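# synthetic laccase/ascorbate-oxidase anchor profile (1-based positions)
reference	LACAAO_REF_SYN
domain	1	110
domain	111	230
domain	231	340
HA1	140
HA2	142
HB1	170
HB2	172
HC1	200
HC2	202
NNX_anchor	180
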