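aa	codon	T_pyriformis	P_caudatum	P_tetraurelia
Ala	GCG	0.03	0.03	0.08
Ala	GCA	0.32	0.41	0.20
Ala	GCT	0.57	0.54	0.30
Ala	GCC	0.07	0.02	0.41
Cys	TGT	0.86	0.85	0.24
Cys	TGC	0.14	0.15	0.76
Asp	GAT	0.81	0.81	0.36
Asp	GAC	0.19	0.19	0.64
Glu	GAG	0.08	0.17	0.70
Glu	GAA	0.92	0.83	0.30
Phe	TTT	0.89	0.95	0.62
Phe	TTC	0.11	0.05	0.38
Gly	GGG	0.03	0.05	0.27
Gly	GGA	0.16	0.19	0.20
Gly	GGT	0.78	0.73	0.16
Gly	GGC	0.03	0.04	0.37
His	CAT	0.69	0.69	0.31
His	CAC	0.31	0.31	0.69
Ile	ATA	0.62	0.42	0.21
Ile	ATT	0.33	0.53	0.33
Ile	ATC	0.06	0.05	0.46
Lys	AAG	0.04	0.11	0.64
Lys	AAA	0.96	0.89	0.36
Leu	TTG	0.03	0.09	0.13
Leu	TTA	0.75	0.74	0.14
Leu	CTG	0.01	0.01	0.09
Leu	CTA	0.13	0.05	0.15
Leu	CTT	0.07	0.11	0.19
Leu	CTC	0.01	0.01	0.31
Met	ATG	1.00	1.00	1.00
Asn	AAT	0.79	0.77	0.34
Asn	AAC	0.21	0.23	0.66
Pro	CCG	0.07	0.03	0.03
Pro	CCA	0.36	0.42	0.16
Pro	CCT	0.54	0.51	0.27
Pro	CCC	0.03	0.04	0.54
Gln	CAG	0.06	0.14	0.58
Gln	CAA	0.94	0.86	0.42
Arg	AGG	0.02	0.17	0.45
Arg	AGA	0.95	0.74	0.16
Arg	CGG	0.00	0.00	0.03
Arg	CGA	0.00	0.02	0.11
Arg	CGT	0.02	0.06	0.06
Arg	CGC	0.00	0.01	0.18
Ser	AGT	0.21	0.24	0.07
Ser	AGC	0.06	0.09	0.27
Ser	TCG	0.03	0.03	0.12
Ser	TCA	0.32	0.20	0.10
Ser	TCT	0.34	0.42	0.24
Ser	TCC	0.04	0.03	0.20
Thr	ACG	0.01	0.03	0.22
Thr	ACA	0.53	0.45	0.18
Thr	ACT	0.41	0.49	0.23
Thr	ACC	0.06	0.03	0.37
Val	GTG	0.04	0.06	0.19
Val	GTA	0.49	0.35	0.20
Val	GTT	0.42	0.55	0.30
Val	GTC	0.06	0.04	0.31
Trp	TGG	0.03	0.01	0.48
Trp	TGA	0.97	0.99	0.52
Tyr	TAT	0.82	0.79	0.38
Tyr	TAC	0.18	0.21	0.62
Stop	TAG	0.00	0.00	0.39
Stop	TAA	1.00	1.00	0.61
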