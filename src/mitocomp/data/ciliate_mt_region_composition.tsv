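region_class	base	T_pyriformis	P_caudatum	P_tetraurelia
protein_coding	G	10.3	12.1	19.5
protein_coding	A	41.1	35.5	24.8
protein_coding	T	38.7	42.8	32.0
protein_coding	C	9.9	9.6	23.7
noncoding	G	6.2	8.0	18.7
noncoding	A	40.8	35.7	24.3
noncoding	T	46.3	49.0	36.1
noncoding	C	6.7	7.3	20.9
rRNA	G	13.8	19.0	21.2
rRNA	A	35.3	35.6	33.0
rRNA	T	35.7	32.3	30.3
rRNA	C	15.2	13.1	15.5
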