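>TYROSINASE
MSCRQAMIIRIIFCSRSLNHPVEHEQYKYHNPSVWHEAVLYNTFHFHMCFLNARRACAYS
GERQFFYYFYGFQDVRLFMHGQLHIVDKNKYNRRHFPDGEGWFITCPMHIQNAWWPSFNT
>PPO1_DWL
HISWKCQGVDPMIYPNAVASIPHHMWLMSMEGYNPPLLVWGNSPWQRPEWLILVWLGRVG
YMRRRWGMGVSWKTEAPTLVTTHPFMIMGEGVAALTDDSD
>PPO1_KFDV
CLVIVSQIHRSMAIWAIWHSREHQWDNEWICAHKIPVGHKFDVEMCDAHYYRDQMFCYRP
SPHRFVLWSYNCYCVEEVMAMIERCTARQHRFQEDFHNKYWEMRPDRYNP
>CU_OXIDASE_3
RPMQDLTEKTLHFHGVWFHIPNKDFIMWADVSVAANQDHVMARSAFDQYFMHWETTFYPT
PWERNPRWFLKAYYQNWFRDSMKQPFWYNTPKQCYHPGSNQSHPIVLRRC
>CU_OXIDASE
SAGPGFRFQNFHSCRPMDSHTAYWAMCFWHMHRGHSHMKFNTKMKECCFQVNWDRCRNDH
PHPHTAEPQNNSGTEDGYPKMWKLKCQSVHEHMDPQHHSIDPDPFKTQMANDEFQTYVNL
>CU_OXIDASE_2
HMSHYVSPEMRSAIFCTNTLCFHGPYGINIATSDDQTRWANGMHTNELDKVTTLTVQYDD
IFWIKHNHVYEYKIWQVTLRWLHVNKYCLNYTGNNQLPIITNCIQVNVKK
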