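amino_acid	codon	frequency	rscu
Phe	UUU	66	0.675714
Phe	UUC	142	1.324286
Leu	UUA	28	0.268571
Leu	UUG	71	0.732857
Leu	CUU	127	1.09
Leu	CUC	101	1.011429
Leu	CUA	53	0.468571
Leu	CUG	239	2.428571
Ile	AUU	34	0.801429
Ile	AUC	67	1.28
Ile	AUA	34	0.918571
Met	AUG	110	1
Val	GUU	65	0.861429
Val	GUC	47	0.715714
Val	GUA	39	0.522857
Val	GUG	122	1.902857
Ser	UCU	89	1.078571
Ser	UCC	104	1.27
Ser	UCA	70	0.904286
Ser	UCG	23	0.317143
Pro	CCU	157	0.974286
Pro	CCC	256	1.641429
Pro	CCA	124	0.75
Pro	CCG	102	0.635714
Thr	ACU	74	0.795714
Thr	ACC	134	1.365714
Thr	ACA	108	1.142857
Thr	ACG	64	0.697143
Ala	GCU	128	1.047143
Ala	GCC	199	1.585714
Ala	GCA	99	0.735714
Ala	GCG	79	0.631429
Tyr	UAU	30	0.678571
Tyr	UAC	75	1.321429
His	CAU	92	0.74
His	CAC	148	1.26
Gln	CAA	144	0.864286
Gln	CAG	132	1.135714
Asn	AAU	40	0.787143
Asn	AAC	75	1.212857
Lys	AAA	58	0.822857
Lys	AAG	138	1.178571
Asp	GAU	94	0.835714
Asp	GAC	131	1.164286
Glu	GAA	116	0.944286
Glu	GAG	121	1.055714
Cys	UGU	73	0.69
Cys	UGC	151	1.31
Trp	UGG	206	1
Arg	CGU	34	0.428571
Arg	CGC	104	1.327143
Arg	CGA	68	0.772857
Arg	CGG	92	1.177143
Ser	AGU	66	0.897143
Ser	AGC	112	1.534286
Arg	AGA	109	1.212857
Arg	AGG	93	1.08
Gly	GGU	71	0.527143
Gly	GGC	207	1.371429
Gly	GGA	156	1.074286
Gly	GGG	149	1.03
TER	UAA	21	0.374286
TER	UAG	21	0.425714
TER	UGA	132	2.201429
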