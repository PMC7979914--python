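group	pk	sign
D	3.65	-1
E	4.25	-1
C	8.18	-1
Y	10.07	-1
H	6.00	1
K	10.53	1
R	12.48	1
Nterm	9.69	1
Cterm	2.34	-1
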