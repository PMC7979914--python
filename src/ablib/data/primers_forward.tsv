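primer_id	sequence	intended_family	intended_genes	orientation
IGHV1a	CAGGTKCAGCTGGTGCAG	IGHV1	IGHV1-46,IGHV1-69,IGHV1-18,IGHV1-2	forward
IGHV1b	CAGGTCCAGCTTGTGCAG	IGHV1		forward
IGHV1c	SAGGTCCAGCTGGTACAG	IGHV1		forward
IGHV1d	CARATGCAGCTGGTGCAG	IGHV1		forward
IGHV2a	CAGATCACCTTGAAGGAG	IGHV2	IGHV2-5	forward
IGHV2b	CAGGTCACCTTGARGGAG	IGHV2	IGHV2-26	forward
IGHV3a	GARGTGCAGCTGGTGGAG	IGHV3	IGHV3-7	forward
IGHV3b	CAGGTGCAGCTGGTGGAG	IGHV3	IGHV3-30	forward
IGHV3c	GAGGTGCAGCTGTTGGAG	IGHV3	IGHV3-23	forward
IGHV4	CAGSTGCAGCTGCAGGAG	IGHV4	IGHV4-59	forward
IGHV5a	GARGTGCAGCTGGTGCAG	IGHV5	IGHV5-51	forward
IGHV6a	CAGGTACAGCTGCAGCAG	IGHV6	IGHV6-1	forward
IGKV1a	RACATCCAGATGACCCAG	IGKV1	IGKV1-39,IGKV1-33	forward
IGKV1b	GMCATCCAGTTGACCCAG	IGKV1	IGKV1-9	forward
IGKV1c	GCCATCCRGATGACCCAG	IGKV1	IGKV1-5	forward
IGKV1d	GTCATCTGGATGACCCAG	IGKV1		forward
IGKV3a	GAAATTGTGTTGACRCAG	IGKV3	IGKV3-20,IGKV3-11	forward
IGLV1a	GAAATAGTGATGACGCAG	IGLV1	IGLV1-47	forward
IGLV1b	CAGTCTGTGCTGACTCAG	IGLV1	IGLV1-40	forward
IGLV2	CAGTCTGTGYTGACGCAG	IGLV2	IGLV2-14	forward
IGLV3a	CAGTCTGCCCTGACTCAG	IGLV3	IGLV3-21	forward
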