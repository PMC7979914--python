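primer_id	sequence	intended_family	intended_genes	orientation
IGHJ1/2-R	CAATTGGTCGATTCTTCG	IGHJ	IGHJ1,IGHJ2	reverse
IGHJ3-R	CAATTTGACGATTCTCTT	IGHJ	IGHJ3	reverse
IGHJ4/5-R	CCATTGGGCGATCCTTTC	IGHJ	IGHJ4,IGHJ5	reverse
IGHJ6-R	CAATTGGACGATTCTGTC	IGHJ	IGHJ6	reverse
IGKJ1-R	GACACGTCTTACTGAAAT	IGKJ	IGKJ1	reverse
IGKJ2-R	GGCTCGTCTTTCTGATAT	IGKJ	IGKJ2	reverse
IGKJ3-R	GGCGCGTCTGGCTAAGAT	IGKJ	IGKJ3	reverse
IGKJ4-R	CGGGCGTCTTACTGCAAA	IGKJ	IGKJ4	reverse
IGKJ5-R	GGCGCGTCTTGGCATAAT	IGKJ	IGKJ5	reverse
IGLJ1-R	TGCGTTATGGAAAAGACA	IGLJ	IGLJ1	reverse
IGLJ2/3-R	ATTCCTATAAAAAAGACA	IGLJ	IGLJ2,IGLJ3	reverse
IGLJ7-R	ATTGTTATAGAAAAGACA	IGLJ	IGLJ7	reverse
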