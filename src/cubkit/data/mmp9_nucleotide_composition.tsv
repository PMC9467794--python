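species	at_frac	gc_frac	t3s	c3s	a3s	g3s	gc3s	at3s
Bos grunniens	0.366	0.634	0.1842	0.5263	0.1981	0.2891	0.685	0.315
Bos taurus	0.378	0.622	0.173	0.5554	0.1202	0.3781	0.759	0.241
Macaca mulatta	0.379	0.621	0.1766	0.5135	0.1277	0.3978	0.747	0.253
Mus musculus	0.433	0.567	0.2776	0.3436	0.3056	0.2458	0.503	0.497
Oryctolagus cuniculus	0.345	0.655	0.2237	0.3099	0.1976	0.3431	0.606	0.394
Sus scrofa	0.385	0.615	0.1814	0.5411	0.1207	0.3852	0.752	0.248
Canis lupus familiaris	0.373	0.627	0.1554	0.5702	0.1143	0.39	0.779	0.221
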