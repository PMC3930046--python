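EV824350.93	TTCGATACGATAAGCCGCAATGTCTGCAGGAACACTGGCTAAACCCGCAATGCGCGGTCT[A/G]CTCGGTAAACGTCTACGATTCCACCTGGCTGTTGCTTTCACGCTGTCTTTGGCTGCAGCA
ES698489.358	ATTTTAAAGTGGARCCCTTTGTTGTTGATTCCTGGTTTAAATTTCCAGCACCTTCACAAA[A/T]TCCAGTAAGAAAGACATGTGAAGTAGACMSTGGCCGTGTATTTCAGATGTGCTCTGATAA
DR977078.72	TTGCCCAGGTCTTGAACAATATGCTATCAAGAAGTTTGCAGAGGCTTTTGAAGCCATTCC[A/G]CGTGCTCTTGCAGAGAACTCTGGTGTCAAGGGCAATGAACTTATCTCCAAACTGTATGCT
DR976209.314	GAACAGTGCACTCCACAAGAATTGTTTTTAGCCGTATAACTTCAAGAACAGAAAACTAAG[T/C]TGCATTATGAGTGGAGGAAGACAGATGACTGCGCTACTGTACACCCCTTTTACAACAASA
DR977006.239	CTCTTTCACCTTTGAGCTTCGTGATACTGGCAGATATGGATTCCTCCTTCCAGAGTCGCA[A/G]ATCAGGCCAACTTGCCAAGAAACAATGCTGGCAGTCAAATACATTGCCAAACATGTTCAG
EV824380.474	CCAAGGGCAATGTACCGCAACTTCTGGAGCCCATCCCATACGAGTTCATGGCGTAAAGCA[T/C]GGTCAAGCCAGAATAAAGTCCTGTTTTCAACAAAAAAAAAAAAAAAAAAAAANAAANNNA
DR976578.395	TTTCCCCATCAATGTGGTCGTTCAGGAAACTGGGTCTCTGGTGGAAATCAGGAATTTCTT[A/G]GGAGAAAAGTACATCCGCAGAGTACGCATGAGGCAGGGTGTGACCTGTAATGTTTCCCAG
DR975536.188	TAGAAGAGGGCGCCTGACCAAGCACACCAAGTTYGTTCGGGACATGATCCGCGAGGTGTG[T/C]GGCTTCGCCCCCTACGAGAGACGCGCCATGGAGCTGCTGAAGGTCTCCAAGGATAAGCGM
DR977561.396	GAAGTTTGCCTGCAATGGGACTGTGATTGAGCATCCAGAATATGGTGAAGTGGTTCAGCT[A/G]CAGGGTGATCAGCGCAAGAATATCTGCCAGTTCCTTACTGAGATTGGCTTGGCTAAGGAG
ES698197.350	AACAAGCCAAGGACAAGCCCCAGGAGAAACCCAAATAACATGGCAAGAGRACTAACCATC[A/G]CTTACAAGAGAAGTTTCAATCTCCGACACAAGCTTCCTGTCTGGGATTTCATTTTCMTTT
DR974886.648	TTGGTACCGTGTATCTCTCTGCTCTGGCTTTATAATGATGGGTGTCACCGTATATGAAGG[A/G]GGCACCTGGTAATGCASATGGTAAACCAATCAGTAATGTAAAGAATTGGATGCAATAAAG
ES697699.316	GAGAAGATYGACCTGAAGTTCAACCACCTCCAAGTTCGGACACGGACGCTTCCAGACCGC[T/C]GAAGAGAAGAAGGCGTTCATGGGACCACTCAAAAAGGACCGAATCCTCAAGGAGGAGACT
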