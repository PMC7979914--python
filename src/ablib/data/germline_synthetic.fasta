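>IGHV1-2
CAGGTGCAGCTGGTGCAGCTTAAGTTTACCTATCTATTACCGATATGTTGCGCTCAGGCACCAATTCGATCCGTACACGTGATTCGTATGTGCCCCACTGGCTACCTTCATCGTAAAACGTTGTGGGGGGGTATTTCTAGCACCAAGTTATCCAACCGGCTGACGAACTTGTTTAATATATGTACCCGCCATAGAATGCACACCCGCAAGGTTACATCACAACGCAGCGATTTAGGTCCTGAATTTCCACGTTGTCCAGGTGGCGTGTCCGTCGTTATATATTGCTGGTGC
>IGHV1-18
CAGGTTCAGCTGGTGCAGCTTACGTGTACCTATCTATTACCGATATGTTGCGTTCAGGCACGAATTCTATCCGTACTCGTGATCCGGATGTGCGCCACTCGCTACCTTCATAGTAAAACGTTGTGGGGGGGTATTTCTGGCACCAAGTCATCGAACCGGCTAATGAACTTGTTTAATAAATGTACCCGCCATAGTATGCACACACGCAAGCTTACATCACTACCCAGCGATTTATGGCCTGAGGTTCCGCTTTTCCCAGGTAGCATGTCCGTCGTTATCTTTTGCTGGTGC
>IGHV1-46
CAGGTTCAGCTGGTGCAGATTAACTTTGCCTATCTATTACCGATATGTAGCGTCCAGGCACCAATTCGATCCGTACTCGTTATTCGGCTGTGCCCCACTCGCTACCTTCATTGTAAAACGTTGTGGCGGGGTATTTCCGGCACCAAGTTATCGAACCGTCTAATGAACTTGTTTAATATACGTACCCGCCATAGAATGCACACCCGCAAGATCACATCACTACGCAGCGATTTATGGCCTGAGGTTCCACGTTGGCCAGGTGGGATGTCCGTCGTTATCTGTCGCTCGTGC
>IGHV1-69
CAGGTGCAGCTGGTGCAGCTTAAGCTGACCTATCTATTACCGATATGTTGCGTTCAGGCGCCATTTCGATCCGTACTCGTGCTTCGGATGTGCCCCACTCGCTACATTCTTTGTAAAACGTTGTGGGGGGGTATTTCTGGCACCAATTTATGGAACCGGCTAATGGACTTGTTTATTATATGTACTCGGCATAGAATGCGCACACCCAAGATTACATCACTACGCAGCGATTTATGGCCTGAGGTTCCACGTTGTCCAGGCGGCATGTCAGTCGTTATCTATGGCTGGTGC
>IGHV2-5
CAGATCACCTTGAAGGAGAGTGCACTTTTATTGACTTTCGCGGCAGGACCCACCAGATTACAAACCCATCAAATTAGCCGCTTACTGACTATTCGGATCGAAACCCTCGGTTTATATAGGCCGTGGTGGTATCGATCACCGCTAATAGTTCGTCGCAAAAACAATGTAAAGGGACGCAGTAAAACAATGGAGCGATCAAAAACTTGGTCAATGATCACCCTACTACATCGCTCCAGTGCCACGTTACTCAGCGTACAGGTAAATAATTGGCAGTTAGTTAAGACCTTGTGC
>IGHV2-26
CAGGTCACCTTGAGGGAGTCTGCACTTTTAGTGACTTTCGCGGCAGGACCCAACGGATTAGAATCCCAACAAACTAGCCTCTTACTGACTATTCGGATCTCAACCCTCGGCTTATATAGGCCGTGGAGGTATCGATCACCGCTATTGGTGCGTCGCAAAAACAACGTAGAGGGAGGCAGTAAAACAATTGAGCGATCAAAAACTTGGTCAATGATCAGCCTACTACCTCGCTCCAGAGCCACGTTAGGGATCGTACAGGTATATGATTCGCAGTTACTTCAGACGATGTGC
>IGHV3-7
GAGGTGCAGCTGGTGGAGGTCTTCGTTGTATTGCGAACGGGTCTGCGGTCCTGTCTTCAAAGTCAAAATGAAGTGGTGCGGAGCCAAGGGCGCATTCGCAGGCTGACCCTGCCCTCTCTAATAGCTTCGCCTATCCCCACGACGAGCCACGCCAAGTCGGATTTCGAGTCGGCCATTTGCAGTCGCGACGCCTATCAAATAACATCACGCACGTTAACTCGTAACACAATCCGGATGTTATCGATACAGGCGCTGTTACGCATAACGAGGAGCCCGCGGAACAGGGATTGC
>IGHV3-23
GAGGTGCAGCTGTTGGAGGTCTTCGTTGATTTGGGAACGGGTCAGCGGTCCTATCTTCAAAGTAAACCTGAAGTGGTGCGGAGACAGGGGCGCACTCGCAGGCTGACCCTGCCCTCTCGAATATCTCCGCCAATCGCCACGACGAGCCGCTCGGAGTCGGACTTCCAGTCGGCCACTTGCAGTCTGGACGCCTATCAAATAACCTCACGCACGTTATCTGGTAACACAATCCGGTTGTTATCGATACAAGTGCTATTACGCATAACGACGAGCACGCGGAACAGGGATTGC
>IGHV3-30
CAGGTGCAGCTGGTGGAGGTCTTCGTTGAAGTGGGAACGGGTATGCGGTCCTATCTTCACAGTATAACTGAAGTGGTGCGGCGACAAGGGCGCGTTCGCAGGGTGACCGTGCCCTCTCGAATAGCTCCGCCTATCCGCACGACGAGGCGCGCGAAGTCGGATTTCCAATCCGCCACTTGCAGTCTTTACGCCTATCAAATAACCTCACGCACGTTAACTGGTAACACAATCCGGATGTTATCAATACAGGTGCTGTTACGCAGGACGACGAGCCCTCGGAACAGGGATTGC
>IGHV4-59
CAGCTGCAGCTGCAGGAGCGCCAGCTGGACTCTAGAACATGGCTTGAACGTGCTTATCTAGACGCAAGGCGACTATACAAAATAGTACCGGGATGTCAATTAGTCAGCATTGTAAACAGTAGGGAAGACTCTGGCCGTCCCCAGGACATGCACAATGAGCCGCGCTTTAGCCGGATCTACTCCTTAGGTTTCCCATTGACATGGATGCGAAGAATCGGCCTTGGTAGGCCTTACAGCTCCTATTGGCAAAAGAGGGTCGTGAGCTCTACCCCTGCCCCCACTATCAGCTGC
>IGHV5-51
GAAGTGCAGCTGGTGCAGGAGCTTCCGCCTTGCGGTCGTCGTCGGGCTGTAGCGATCCATGATAGGCTTTATCGACTTAGCGCAGATGAATATTCCCGCGCACTACTTGGGCACGGGAGGCTCTGGTCGATATCAAACATCGTGTTTATATCTCACTCACCGCACAGCAGGTCCAGAGGTTTGATAGTTCGCAATTGCGCAGGGTTGTCCTTTGCCAGCAAGGTAAGCAAGCCATGTCCAACAGACAGACCATTTTTAGTACGAATGCCTGGTGGATCCCAGAGATCATGC
>IGHV6-1
CAGGTACAGCTGCAGCAGGATGTGCCATCCAGAGAACGTGTGGGGCTGGTGCCACACCTAAGCGGACGACCTGATCTTTTTTGTCCCGTAACTGGTTGTACGAGTTTTACCGCTAACTGGGTTGGTCTTTCGCAAGTTCGATGTATGGGACCCATAGTTGCAGCGACGGTCTCTACGGATGCACCAGTTGAAGTCGCCAAAACTCAATCTCCTAGGCCCGCCCGAGGACAGGCATGCGTAGCTGGCTGGAAATATCAAGTAAAAGCGTTGTTGGCGAAGAGGTACCTTTGC
>IGKV1-5
GCCATCCGGATGACCCAGCTTACGTATTTCGGACACCATTGTATAACCTGCACGCACAAGACGCCGCCCGCGAGCTCAGACATCTTATGCCGGCATAACGCGCACTGGTGGGCATATTTCGTTTTCCCTGAGGGCGACGTACCATATTCGTATACCTTGTATGTCGCTATCGCTCGGGGCGTCTGTCGGCAGGCGCTGGGAGAGGCTGTTCAAGAGTATAGAACTAAGGGGCGGATCCATAGGACACAGTCTTGCGGGCCCTCACATAGGTCGGGCCCCATACCCTTCTGC
>IGKV1-9
GCCATCCAGTTGACCCAGCTCACGTATTTCGGACACCATTGTATAACCTGCACCCTCGAGACGCCGCCCGCGGGCTCAGACGTCCTATGCCGGCATAACGCGCACTGGTGGGCATATTTCTTTTTCCCTGAGGGCGAAGTACCATATTCGTATACCTTGCATGTCGCGCTGGCTCGGGGCGTCTGTCGGCAGTCGCTAGCAGAGGCTGTTAAAGAGCATAGAACTAAGTGCCGGAAACGTAGGACACAGTGTTGCGGCCCCTCACATAGCTGGGGGCCCACATCTCGCTGC
>IGKV1-33
GACATCCAGATGACCCAGCTTCCGGACTTCGGACACCATTGTTTAACCTGCACGCACCAGACGCCGCCCGCGGGCTTAAACATCTTATGCCGGCGTAACGCGCACTGGTGGGCATATTTCTTTTTCCCGGAGGGCGAAGTACCATATTCGTATTCCTTGCATGTCGCTCTGGCTTGGGGCGTCGGTCGGCAGGCGCTGGCAGTGGCTGTTAAAGAGTATAGAACTGAGTGGCGGATCCGTAGGACACAGTGTGGCGGGCGCTCACATAGCTCGGGGCCCACACGCGTATGC
>IGKV1-39
AACATCCAGATGACCCAGCTTACGAATTTCGGACACCGTTGTATAACCTACACGCACGAGAAGCCGCCCGCGGGCTCAGTCATCTTATGCCGGCATAACGCGCACTGGTGGGGAAAGTTCTTTTTCCGTGAGGGCGAGGTTCCATATTCGTATACCTTGCATGTCGCTCTGGCTTGGGGCGTCTGTCTGCAGGCGATGGCAGAGGCTGTTAATGAGTATAGAACTGAGTGGCGGCTCCGTAGGACACAGTGTTGCGGGCCCTCACATAGCTCGGGGCCCACATGTGTCTGC
>IGKV3-11
GAAATTGTGTTGACACAGCGGAGGTTCTCGGCAGACCTAGGACTTAATGCGATACTTGTTCGGGTATTCCAGCGACCGGAGCTCTCTGAACCAGGCACCTACCGGTACCAGGATACCGACACTGCAAAATGGTGGTTAGCTCTAGGTGTCGCGAATGTCACCGAGTTACGTCGGCAGAATTTTTGGTGGTTGCCTTCCCACCCGGCAAGCGAACCCCCTACGCCTTCTGGGAACTCAAGATGGACCAGGGACGGTTACATCAAGCGTGTGAGTGCTATCGGTATAGTCTGC
>IGKV3-20
GAAATTGTGTTGACACAGCGCAGGTTCACGTCAGACCTGGGACTTTATGCGATACTTGTTCGGCTATTGCGCCGACCGGAGTTTTTTGAACAAGGCACCTACCGGTCCCAGGATACCGACTCCTCAAAATGGTGTTTAGCTCTAGGTGTCGCCAATGACACCGAGTTAGGACTGGAAAATTTTTGTTGGGTTCCTTCCCACCCGGCAGGCGGACCTCCTACGCCTTCTGGGAACTCAAGATGGACCAGGGACGGTTTCATCAAACGTGTGCGTGCTATCGGTGTAGTCTGC
>IGLV1-40
CAGTCTGTGCTGACTCAGACCAGGTTGACTCAAATTCGATCACGCCACTCATCGAAAATAAGCGGACCAAACCCCCTCGTCGGGAGCGAGGTATTAGTTCGGTCCACGATCGTCTATCGCCCAGTGCACGTGTCGCTTCGTGAGCCGGGCCACGTCGCCACAAGCATAGCATTCAAGGATAAAACGCCGGGGCCTAAGGCCTTAGTGTATTGGAATCAATCTCGGAAAGGGTGTGTGTTTCAGAGCAATACCTTTAACACCCGGGTTGTACCAACTATGGCAAAATCCTGC
>IGLV1-47
GAAATAGTGATGACGCAGACCAGGTTGACTCAAATTAGATCGAGCCACTCATGGAAAATAAGAGGACAAAACCTCCTCGTTGCGAGGGAGGTATTTGTTCGGTCGACGATCGTCTATCTCCCAGTGCAGGTGGCGCTCCGTGAGCCAGACCACGCCGCAACAAGCATAGCATTCAAGGCTAAAACCCATGGGCATAACGCCTTAATGTATTGGAATCAACCTAGGAAAGAGTGTTTGTTTCAGAGCATTACCTTTTACACCCGGGTTGTACCAACTATGGCAAAATCCTGC
>IGLV2-14
CAGTCTGTGTTGACGCAGATACACGCTTGTCTCTCTACTAGGTCTCCTTTAGAAAACATCGCGTTTCTAGATGAGTTAAGGACAGAACGACGGACCCTAGTTGCAAAGTCGAGAGGCCACTACGTTACGTATAGACCTGGACTAGGTGGCTCTTACTGGGGTTCTCATCTATCATCGAAAGGTATAGTTACCTCTCCGCCGGCACCCCAAATTTCAGGTGTACTCAGACTGTCTGGAGCTAACCAGCAATGTAGTTCTTCCTATCTTCCTGTTGCCTATGTCGTGGATTGC
>IGLV3-1
CAGTCTGCCCTGACTCAGCCTCTATTTATGAAGTCGGCGGCCTCCGTTTTGGCTACCGGATCGTCGTTGGCGAGGGTATTGTGTAACCCCTTTTACACCGCGAGTAATGTGAATCTATCGCGGCCTACATCTAAATGTATGGTTAAGGATCGGGATCAAGGGCTGACCCCTTGTTTTGCGCTACGAATAGCGTATTCAACCCATAGCAGCTGGTTCGGGAGTTGGGGGCTACGAGAAGCACGTGCTTGGCGATTGCTATGTAGCTCCGCTTGTATTCTCATCCCGCGCTGC
>IGLV3-21
CAGTCTGCCCTGACTCAGGCTCCATTTATGGAGTCGGCGGCCTCCGTTTTGGCCACCGGATCGTCTTGGGGGACGTTATTCTGTTACCCCTTTTACACCGCGAGTAGTGTGGATCTATGGCGCCCTGCTTCGATATGTATGGTTAATGATCGGGATCAAGGGGTGACCCCTTGTTTTGCGTTAGTAAAAGCGTATCCAACGCATAGAAGCTATTTCGGGAGTTGGGGGCTACGAGAAGCCCGTGCTGGGCAATTGCTATGTAGCTGCGCTTTTAATCTCATCCCGCGCTGC
>IGHJ1
TGGCCTCCACTCAACGTCCGAAGAATCGACCAATTG
>IGHJ2
TGGGCTCAAACCTCAGTCGAAATAACCGTCCAATTG
>IGHJ3
TGGCCTCCACCCTATGCCAAGAGAATCGTCAAATTG
>IGHJ4
TGGCGCCCACCCTACGTCGAAAGGATCGCCCAATGG
>IGHJ5
TGGTCTTCACCCTACGTCGAAACAACCTTCAAATCG
>IGHJ6
TGGCTTTCATCCTACTTCGACAGAATCGTCCAATTG
>IGKJ1
TTCGTCTGGATTATTTCGATTTCAGTAAGACGTGTC
>IGKJ2
TTCGATTTCATTATGTCGATATCAGAAAGACGAGCC
>IGKJ3
TTCGACATTATGATGTCGATCTTAGCCAGACGCGCC
>IGKJ4
TTCGTCTTGATTATGTCGTTTGCAGTAAGACGCCCG
>IGKJ5
TTCGAGTTGATTATATCGATTATGCCAAGACGCGCC
>IGLJ1
TTCTATGTGGGATGGAACTGTCTTTTCCATAACGCA
>IGLJ2
TTCTATGTGAATAGGAAATGTCTTTTTTATAGGAAT
>IGLJ3
TTCTATGTGAGAGGTAAATGTATTTGCTCTTACAAT
>IGLJ7
TTCTATATGTGTCGGCAGTGTCTTTTCTATAACAAT
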