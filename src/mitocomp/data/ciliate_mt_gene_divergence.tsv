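gene	gene_class	length_aa	identity	kaks
cob	known	442	0.91	0.012
cox1	known	745	0.93	0.019
cox2	known	577	0.84	0.022
atp9	known	75	1.00	0.001
yejR	known	447	0.47	0.242
nad1_a	known	287	0.93	0.012
nad1_b	known	63	0.71	0.027
nad2	known	167	0.67	0.093
nad3	known	120	0.83	0.033
nad4	known	501	0.70	0.062
nad4L	known	115	0.64	0.070
nad5	known	597	0.75	0.049
nad6	known	256	0.73	0.064
nad7	known	423	0.91	0.010
nad9	known	184	0.67	0.072
nad10	known	154	0.95	0.006
rps3	known	363	0.57	0.195
rps12	known	139	0.84	0.024
rps13	known	244	0.66	0.049
rps14	known	102	0.59	0.104
rps19	known	88	0.46	0.188
rpl2	known	265	0.68	0.523
rpl6	known	178	0.71	0.055
rpl14	known	119	0.75	0.030
rpl16	known	166	0.74	0.047
ymf56	orf	81	0.73	0.067
ymf57	orf	105	0.77	0.069
ymf59	orf	127	0.40	0.340
ymf61	orf	189	0.40	0.298
ymf63	orf	525	0.44	0.258
ymf64	orf	1712	0.56	0.168
ymf65	orf	365	NA	NA
ymf66	orf	412	NA	NA
ymf67	orf	354	NA	NA
ymf68	orf	395	0.76	0.044
ymf76	orf	399	NA	NA
ymf78	orf	69	0.48	0.298
ymf79	orf	73	0.38	0.323
ymf80	orf	97	0.68	0.076
ymf83	orf	168	0.55	0.206
ymf84	orf	158	0.33	0.291
ymf87	orf	107	NA	NA
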