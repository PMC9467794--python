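amino_acid	codon	frequency	rscu
Phe	UUU	72	0.584285714
Phe	UUC	197	1.415714286
Leu	UUA	17	0.17
Leu	UUG	44	0.621428571
Leu	CUU	76	0.848571429
Leu	CUC	107	1.362857143
Leu	CUA	33	0.357142857
Leu	CUG	195	2.641428571
Ile	AUU	30	0.811428571
Ile	AUC	61	1.881428571
Ile	AUA	11	0.308571429
Met	AUG	49	1
Val	GUU	48	0.684285714
Val	GUC	66	0.957142857
Val	GUA	29	0.375714286
Val	GUG	147	1.978571429
Ser	UCU	75	0.994285714
Ser	UCC	118	1.862857143
Ser	UCA	41	0.494285714
Ser	UCG	55	0.832857143
Pro	CCU	117	0.85
Pro	CCC	209	1.644285714
Pro	CCA	108	0.735714286
Pro	CCG	102	0.774285714
Thr	ACU	74	0.688571429
Thr	ACC	208	2.145714286
Thr	ACA	54	0.484285714
Thr	ACG	82	0.684285714
Ala	GCU	84	0.792857143
Ala	GCC	175	1.731428571
Ala	GCA	71	0.655714286
Ala	GCG	87	0.815714286
Tyr	UAU	35	0.54
Tyr	UAC	119	1.46
His	CAU	39	0.441428571
His	CAC	116	1.558571429
Gln	CAA	62	0.537142857
Gln	CAG	136	1.462857143
Asn	AAU	33	0.664285714
Asn	AAC	72	1.335714286
Lys	AAA	41	0.598571429
Lys	AAG	105	1.401428571
Asp	GAU	70	0.571428571
Asp	GAC	210	1.428571429
Glu	GAA	72	0.592857143
Glu	GAG	159	1.407142857
Cys	UGU	46	0.417142857
Cys	UGC	135	1.582857143
Trp	UGG	128	1
Arg	CGU	45	0.532857143
Arg	CGC	134	2.072857143
Arg	CGA	54	0.667142857
Arg	CGG	77	0.965714286
Ser	AGU	31	0.418571429
Ser	AGC	91	1.395714286
Arg	AGA	63	0.752857143
Arg	AGG	79	1.011428571
Gly	GGU	77	0.615714286
Gly	GGC	219	1.738571429
Gly	GGA	86	0.654285714
Gly	GGG	124	0.991428571
TER	UAA	18	0.571428571
TER	UAG	20	1.538571429
TER	UGA	37	0.89
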