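species	accession	total_bp	coding_bp	protein_coding_bp	pct_g	pct_a	pct_t	pct_c	gc_pct	gc3_pct	nc	rare
P_caudatum	FN424190	43660	41091	36585	9.9	42.7	34.9	12.5	22.4	12.8	33.5	23
P_tetraurelia	NC001324	40469	NA	NA	NA	NA	NA	NA	41.2	56.5	52.1	5
T_pyriformis	NC000862	NA	NA	NA	NA	NA	NA	NA	NA	11.9	31.5	28
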