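aa	codon	n	percent	rscu
Stop	UAA	0	0	0
Stop	UAG	0	0	0
Ala	GCU	39	1.16	3.06
Ala	GCG	1	0.03	0.08
Ala	GCC	1	0.03	0.08
Ala	GCA	10	0.30	0.78
Cys	UGU	16	0.47	1.68
Cys	UGC	3	0.09	0.32
Asp	GAU	38	1.13	1.73
Asp	GAC	6	0.18	0.27
Glu	GAG	10	0.30	0.31
Glu	GAA	55	1.63	1.69
Phe	UUU	516	15.28	1.90
Phe	UUC	28	0.83	0.10
Gly	GGU	30	0.89	1.29
Gly	GGG	14	0.41	0.60
Gly	GGC	2	0.06	0.09
Gly	GGA	47	1.39	2.02
His	CAC	4	0.12	0.17
His	CAU	42	1.24	1.83
Ile	AUU	359	10.63	1.87
Ile	AUC	26	0.77	0.14
Lys	AAA	150	4.44	1.86
Lys	AAG	11	0.33	0.14
Leu1	CUA	22	0.65	1.42
Leu1	CUC	0	0	0
Leu1	CUG	3	0.09	0.19
Leu1	CUU	37	1.10	2.39
Leu2	UUA	385	11.40	1.86
Leu2	UUG	28	0.83	0.14
Met	AUG	29	0.86	0.15
Met	AUA	363	10.75	1.85
Asn	AAC	24	0.71	0.17
Asn	AAU	262	7.76	1.83
Pro	CCU	53	1.57	3.21
Pro	CCG	0	0	0
Pro	CCC	4	0.12	0.24
Pro	CCA	9	0.27	0.55
Gln	CAG	2	0.06	0.14
Gln	CAA	26	0.77	1.86
Arg	CGA	16	0.47	2.29
Arg	CGC	0	0	0
Arg	CGG	0	0	0
Arg	CGU	12	0.36	1.71
Ser1	AGC	8	0.24	0.22
Ser1	AGA	65	1.93	1.75
Ser1	AGG	0	0	0
Ser1	AGU	39	1.16	1.05
Ser2	UCA	48	1.42	1.29
Ser2	UCC	8	0.24	0.22
Ser2	UCG	1	0.03	0.03
Ser2	UCU	129	3.82	3.46
Thr	ACA	35	1.04	1.46
Thr	ACC	2	0.06	0.08
Thr	ACG	2	0.06	0.08
Thr	ACU	57	1.69	2.38
Val	GUC	1	0.03	0.04
Val	GUG	2	0.06	0.08
Val	GUU	51	1.51	2.13
Val	GUA	42	1.24	1.75
Trp	UGA	44	1.30	1.91
Trp	UGG	2	0.06	0.09
Tyr	UAC	17	0.50	0.22
Tyr	UAU	140	4.15	1.78
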