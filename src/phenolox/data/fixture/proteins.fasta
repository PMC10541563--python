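>syn0000
FGDNKGQCMGMSCRQAMIIRIIFCSRSLNHPVEHEQYKYHNPSVWHEAVLYNTFHFHMCF
LNARRACAYSGERQFFYYFYGFQDVRLFMHGQLHIVDKNKYNRRHFPDGEGWFIYCPMHI
DNAWWPSFNTFNKVKEEMHVFEMMAGEHISWKCQGVDPMIYPNAVASIPHHMWLMSMEGY
NPPLLVWGNSPWQRPEWLILVWLGRVGYMRRRWGMGVLWKTEAPTLVTTHPFMIMGEGVA
ALTDDSDIMPKLHSWMSRKEYPLTFQ
>syn0001
VGNAMRQIQMDESNRNGRPMQDLTEKTLHFHGVWFKIPNKDFIMWADVSVAANRDHVMAR
SAFDQYFMHWETTFYPTPWERNPRWFLKAYYQNWFRDSYKQPFWYNTPKQCYHPGSNQSH
PIVLRRMCMVYYCYFMDSFTFSAGPGFRFQNFHSCRPMDSHTAYWAMCFWHMHRGHSHMK
FNTKMKECCFQVNWDRCRMDHPHPHTAEPQNNSGTEDGYPKMWKLKCQSVHEHMDPQHHS
IDPDPFKTQMSNDEFQTYVNLRWQQFGTAKLQKRCPYMNGHMSHYVSPEMRSAIFCTNTL
HFHGPYGINIATSDDQTRWANGMHTNELDKVTTLTVQYDDIFWIKHNHVYEYKIWQVTLR
WLHVNKYCLNYTGANQLPIIVNCIQVNVKKDEYGEWQH
>syn0002
MTHQHFAMSRMSCRQAMIIRIIFCSRSLNHPVEHEQYKYHNPSVWHEAVLYNTFHFHMCF
LNARAACAYSGERQFFYYFYGFQDVRLFMHGQLHIVDKNKYNRRHFPDGEGWFITCPMHI
QNAWWPSFNTSVQVSFLFKPC
>syn0003
HTSPKAGIAIIMTDHLTRPMQDLTEKTLHFHGVWFHIPNKDFIMWADVSVAANQDHVMAR
SAFDQYFMHWETTFYPTPWERNPRWFLKAYYQNNFRDSMKQPFWYNTPKQCYHPGSNQSH
PIVLRRCSVKWCETCRSAGPGFRFQNFHSCRPMDKHTAYWAMCFWHMHRGHSHMKFNTKM
KECCFQVNWDRCRNDHPHPHTAEPQNNSGTEDGYPKMWKLKCQSVHEHMDPQHHSIDPDP
FKTQMANDEFQTYVNLAMFVMNCYSTTRTFQDLRHMSHYVSPEMRSAIFCTNTLCFHGPY
GINIATSDDQTRWANGMHTNELDKVTTLTVQYDDIFWIKHNHVYEYKIWQVTLRWLHVNK
YCLNYTGNNQLPIITNCIQVNVKKRHNCGVFHGRYDFLI
>syn0004
QVCWMAIIKGCEMSCRQAMIIRIIFCSRSLNHPVEHEQYKYHNPSVWHEAVLYNTFHFHM
CFLNARRACAYSGERQFFYYFYGFQDVRLFMHGQLHIVDKNKYNRRHFPDGEGWFITCPM
HIVNAWWPSFNTVFMGQFRLAINDHISWKCQGVDPMIYPNAVASIPHHMWLMSMEGYNPP
LLVWGNSPWQRPEWLILVWLGRVGYMRRRWGMGVSWKTEAPTLVTTHPFMIMGEGVHALT
DDSDYRTDFAWWWCLVIVRQIHRSMAIWAIWHSRETQWDNEWICAHKIPVGHKFDVEMCD
AHYYRDQMFCYRPSPHRFVLWSYNCYCVEEVMAMIERCTARQHRFQEDFHNKYWEMRPDR
YNPCTYWRNYMKMNCCQSSAG
>syn0005
SPEMAYAIPQMQNRPMQDLTEKTLHFHGVWFHIPNKDFIMWADVSVAANQDHVMARSAFD
QYFMHWETTFDPTPWERNPRWFLKAYYQNWFRDSMKQPFWPNTPKQCYHPGSNCSHPIVL
RRCTDWMPWDMSAGPGFRFQNFHSCRPMDSHTAYWAMCFWHMHRGHSHMKFNTKMKECCF
QVNWDRCRNDHPHPHTAEPQNNSGTEDGYPKMWKLKCQSVHEHMDPQHDSIDPDPFKTQM
ANDEFQTYVNLQQQEYVSCRDTKFEWHMSHYVSPEMRSAIFCTNTLCFHGPYGINIATSD
FQTRWANGMHTNELDKVTTLTVQYDDIFWIKHNHVYEYKIWQVTLRWLHVNKYCLNYTGN
NQLPIITNCIQVNVKKRQHWVTEYLFRNRPS
>syn0006
LEVKMVSLNLPWTFWEYKCMMSCRQAMIIRIIFCSRSLNHPVEHEQYKYHNPSVWHSAVL
YNTFHFHMCFLNARIACAYSGERQFFYYFYGFQDVRLFMHGQLHIVDKNKYNRRHFPDGE
GWFITCPMHIQNAWWPSFNTTIGKFNPCKDRMTHISWKCQGVDPMIYPNAVASIPHHMWL
MSMEGYNPPLLVWGNSPWQRPEWLILVWLGRVGYMRRRWGMGVSWKTEAPTLVTTHPFMI
MGEGVAALTDDSDKQTQSGCPYTQNDDDRCMYR
>syn0007
TEATENVTGSQFENMSCRQAMIIRIIFCSRSLNHPVEHEQYKYHNPSVWHEAVLYNTFHF
HMCFLNARRACAYSGERQFFYYFYGFQDVRLFMYGQLHIVDKNKYNRRHFPDGEGWFITK
PMHIQNAWWPSFNTTIRCPMHAWLPVNGPIMLYHISWKCQGVDPMIYPNAVASIPHHMWL
MSMEGYNPPLLVWGNSPWQRPEWLILVWLGRRGYMRRRWGMGVSWKTEAPTLVTTHPFMI
MGEGVAALTDSSDDEDVHTHALAPEIQ
>syn0008
QCMMTAYNEMSCRQAMIIRIIFCSRSLNHPVEHEQYKYHNPSVWHEAVLYNTFHFHMCFL
NARRACAYSEERQFFWYFYGFQDVRLFMHGQLHIVDKNKYNRRHFPDGEGWFITCPQHIQ
NAWWPSFNTPADLQLVLCHISWKCQGVDPMIYPNAVASIPHHMWLMSMEGYNPPLLVWGN
SPWQRPEWLRLVWLGRVGNMRRRWGMGVSWKTEAPTLVTTHPWMIMGEGVAALTDDSDHC
NDIHLHEY
>syn0009
MINMVSIMIHMSCRQRMIIRIIFCSRSLNHPVEHEQYKYHNPSVWHEAVLYNTFHFHMCF
LNARRACAYSGERQFFYYFYGFQDVRLFMHGQLFIVDKNKYNRRHFPDGEGWFITCPMHI
QNAWWPSFNTEWKPALVIIFSAVFAIPHISWKCQGVFPMIYPNAVASIPHHMWLMSMEGY
NLPLLVWCNSPWQRPEWLILVWLGRVGYMRRRWGMGVSWKTEAPTLVTTHPFMIMGEGVA
ALTDDSDPDDEMYERWETHCSFWQDA
>syn0010
MNVQHHQASIVMTVRGWKMSCRQAMIWRIIFCSRSLNHPVEHEQYKYHNPSVWHEAVLYN
TFHFHMCFLNARRQCAYSGEVQFFYYFNRFQDVRLFMHGQLFIVDKNRYNRRHFPDGEGW
FITCPMHIQNAWWPSFNTSAGQLNWGLHISWKCQGVDPMIYPNAVASIPHHMWLMSMEGY
NPPLLVWGNSPNQRPEWLILVWLGRVGYMRRRWGMGVSWKTEAPTLVTTHPFMIMGEGVA
ALTDDSDCNPLQEDSELWDRG
>syn0011
DMQGCGDGQTHKRPMQDLTEKTLHFHGVWFHIPNKDFIMWAFVSVAANQDHVMARSAFDQ
YFMHDETTFYPTPWERNPRWFLKAYYQNWFRDSMKQPFWYNTPKQCYHPGSNQSHPIVLR
RCLWMHRYIHNSAGPGFRFQNFHSCRPMDSHTAYEAMCFWHMHRGHSHMKFNTKMKECCF
QVNWDRCRNDHPHPHDAEPQNNSGTEDGYPKMWKWKCQSAHEHMDPQHHSIDPDPFKTQM
ANDEFQTYVNYCRKFMQLHHMSHYVSPEMRSAIFCTNTLCFHGPYGINIATSDDQTRWAN
GMHTNELDKVTTLTVQYDDIFWIKHNHVYEYKIWQVTLRWLHVNKYCLNYTGNNQLPIIT
NCIQVNVKKGQQYWVITEGDNEKGGKRRM
>syn0012
WHFHNWALITAYWRAARYPMMSCRQAMITRIIFCSRSLNHPVEHEQYKYHNPSVWHEAVL
YNTFHFHMCFLNARRACAYSGERQFFYYFYGFQDVRLFMHGQLHIVDKNKYNRRHFPDGE
GWFITCPMHIQNAWWPSFNTGQMSKRPAHLMEHYSWKCQGVDPMIYPNAVASIPTHMWLM
SMEGYNPPLLVPGNSPWQRPEWLILVWLGRVGYMRQRWGMGVSWKTEAPTLVTTHPFMIM
GEGVAWLTDDSDYWHHKFCILEICLVIVSQIHRSMAIWAIWHSREHQWDNEWICAHKIPV
GHKFDVEMCDAHYYRDQMFCYRPSPHRFVLWSYNCYCVEEVMAMIERCTARQHRFFEDFH
NKYWEMRPDRYNPPISNSEAVTIV
>syn0013
YVHCRGMSQAYFYGTAQKTMSCRQGMIYRIIFCSRSLNHPVEHEQYKYHNRSMWHEAVLY
NTFHFHMCFLNARRACAYSGERQFFYYFYGFQDVRLFMHGQLHIVDKNKYNRRHFPDGEG
WFITCPMHIQNAWWPSFNTDINTNSSQWK
>syn0014
AKQMSAGAICFMMSCRQAMIIRIIFCSRSLNIPVEHEQYKYHNPSVWHEAVLYNTFHFHM
CFLNARRACAYSGERQFFYYFYGFADVRLFMHGQLHIVDKNKYNRRHFPDGEGWFLTCPM
HIQNAWWPSFNTLGFQQSIKFYFHISLKCQGVDPMIYPNAVASIPHHMWLMSMEGYNPPL
LVWGNSPWQRPEWDILVWLGRVGYMRRRWGMGVSRKTEADTLVTTHPFMIMLEGVAALTD
DSDYEWQFCIWMFLGRHDECYICLVIVSQIHRSMAIWAIWHSREHQWDNEWICAHKIPVG
HKFDVEMCDAHYYRDQMFCYRPSPHRFVLWSYNCYCVEEVMAMIERCTARQHRFQEDFHN
KYWEMRPDRYNPTQGRFPFLF
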