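#protein_id	species	class	missing_his	has_kfdv
syn0000	speciesA	CO_DWL	-	0
syn0001	speciesB	MCO	-	0
syn0002	speciesC	TYR_LIKE	-	0
syn0003	speciesA	MCO	-	0
syn0004	speciesB	CO_FULL	-	1
syn0005	speciesC	MCO	-	0
syn0006	speciesA	CO_DWL	-	0
syn0007	speciesB	CO_DWL	HisB1	0
syn0008	speciesC	CO_DWL	-	0
syn0009	speciesA	CO_DWL	HisB2	0
syn0010	speciesB	CO_DWL	HisB2	0
syn0011	speciesC	MCO	-	0
syn0012	speciesA	CO_FULL	-	1
syn0013	speciesB	TYR_LIKE	-	0
syn0014	speciesC	CO_FULL	HisA1	1
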