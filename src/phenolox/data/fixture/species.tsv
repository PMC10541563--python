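#protein_id	species
syn0000	speciesA
syn0001	speciesB
syn0002	speciesC
syn0003	speciesA
syn0004	speciesB
syn0005	speciesC
syn0006	speciesA
syn0007	speciesB
syn0008	speciesC
syn0009	speciesA
syn0010	speciesB
syn0011	speciesC
syn0012	speciesA
syn0013	speciesB
syn0014	speciesC
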