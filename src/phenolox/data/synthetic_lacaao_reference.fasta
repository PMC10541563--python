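>LACAAO_REF_SYN
RPMQDLTEKTLHFHGVWFHIPNKDFIMWADVSVAANQDHVMARSAFDQYFMHWETTFYPT
PWERNPRWFLKAYYQNWFRDSMKQPFWYNTPKQCYHPGSNQSHPIVLRRCSAGPGFRFQN
FHSCRPMDSHTAYWAMCFWHMHRGHSHMKFNTKMKECCFQVNWDRCRNDHPHPHTAEPQN
NSGTEDGYPKMWKLKCQSVHEHMDPQHHSIDPDPFKTQMANDEFQTYVNLHMSHYVSPEM
RSAIFCTNTLCFHGPYGINIATSDDQTRWANGMHTNELDKVTTLTVQYDDIFWIKHNHVY
EYKIWQVTLRWLHVNKYCLNYTGNNQLPIITNCIQVNVKK
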