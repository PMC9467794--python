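species	at_frac	gc_frac	t3s	c3s	a3s	g3s	gc3s	at3s
Bos grunniens	0.415	0.585	0.2093	0.372	0.2081	0.3703	0.637	0.363
Bos taurus	0.384	0.616	0.2638	0.3049	0.34	0.2724	0.488	0.512
Macaca mulatta	0.409	0.591	0.2247	0.3128	0.2741	0.3031	0.551	0.449
Mus musculus	0.433	0.567	0.2974	0.3234	0.3212	0.2566	0.482	0.518
Oryctolagus cuniculus	0.4	0.6	0.1997	0.5452	0.1304	0.3621	0.73	0.27
Sus scrofa	0.393	0.607	0.1871	0.5485	0.1404	0.3488	0.731	0.269
Canis lupus familiaris	0.417	0.583	0.284	0.3302	0.3285	0.2415	0.482	0.518
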