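>CO_REF_SYN
MSCRQAMIIRIIFCSRSLNHPVEHEQYKYHNPSVWHEAVLYNTFHFHMCFLNARRACAYS
GERQFFYYFYGFQDVRLFMHGQLHIVDKNKYNRRHFPDGEGWFITCPMHIQNAWWPSFNT
HISWKCQGVDPMIYPNAVASIPHHMWLMSMEGYNPPLLVWGNSPWQRPEWLILVWLGRVG
YMRRRWGMGVSWKTEAPTLVTTHPFMIMGEGVAALTDDSDCLVIVSQIHRSMAIWAIWHS
REHQWDNEWICAHKIPVGHKFDVEMCDAHYYRDQMFCYRPSPHRFVLWSYNCYCVEEVMA
MIERCTARQHRFQEDFHNKYWEMRPDRYNP
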