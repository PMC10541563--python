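#protein_id	score
syn0000	2.557
syn0002	7.052
syn0004	5.922
syn0006	4.742
syn0007	2.116
syn0008	8.531
syn0009	5.481
syn0010	7.534
syn0012	8.404
syn0013	7.584
syn0014	6.604
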