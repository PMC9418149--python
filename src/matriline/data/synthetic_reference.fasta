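>SYNTH_DLOOP_1232 synthetic stand-in control-region reference
GGCTGCCTTGTCCACCATCACAGGATGTAAGCTGGTCTTATGTCCGCGAGCGTTGAGGCCAATCTCCTGC
TTCACGATTAGTGTCGCTTTCCCTGATCGCTTATTATGCCCTCACTAAATCTCCTATAGTTTGACGATAT
AAGGGTGAAGACTCCGAACTATCAGTCCTTATGTCGAGAAAGCTGTTGTGATGTATCCGATAGGTGCGCG
ACACCCTCGCGACCACACTTTGAGCAATATTCTGATTGTACGCCCGTGGACCTTTACGGGCTGTAAGCAG
ATCGAAACCTGCCAACAGGCAGGCTTCGTGCTACTTAACAGCACCTACGATAGTTGGAAGGAGTGCCAAG
TGTATACTCAGGCCGCGATCCGGCTTTGGAATCATTCGAACCGATGGGTGTCGCACGCGATTTGACTACC
AGATGCGCAATCGCAGCTATCCGGCCCTATAGTTCTTTATTGCGCTGTCGAGGCGGGCACCGGGTTCCGC
TATTTGTGGGGCTCATGGCAGTTCGGTGTGGGGGCTAAGACGCGAAAGAGGCGCAACCTAGTACCACAGG
GAGCATGTCCTTGATAGGTGCTGTTGTTACCGTTCTAGAAAACTCTACTGCTCCGGATGTCCGCCATGGC
CCATCAGGTGCTGGGAAATAGACGATCAAGAGGTAAACTGCTCACTTCGAATCGGGACACAAGAAACAAG
TGTAGTAGCCCAATATAACCGGACGGTGCAACGGCAGTCTGCTAAAAGATATTGGGAAGCAATCAGAACG
GCACCCACTAGTCGGATTGTCTACCGTGAGTTTTCTAGTAGGGATACTAACTGCGACCGCGCCGCATAAG
TTTGTGCGAATAACGACGTCCTACCAATCCTCCAGCAAAGGGGGTTGTTGGTTGCTTGCCGGAATACGCA
AACACTAACGGAAACTTTCTGTGTTATGGTACTAACGGCAACAATACCTAATGACGCCCCCTAGGGCAGG
AGGAGCAACAAGACCGCGTGAGAGGATCGTGACCGGACACCTTCACACACACCGACAAATATTATCGACG
CCGTCCTATCCCCTGCGTCTAGAGAGACCGACGTGATTCTAAGGGATCTGCCTGGTCTAGCTACTTCTGT
TGCTACCCAAGAAATAGGATCAAACATCTTATAGGGCCGGACTCGTCTATCAAGAGGAAAAGATATCCGT
AAGATTACGCAATATTAGTTGCCGGCGCCAATAGGGAGGACC
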