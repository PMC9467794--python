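species	enc	cai	cbi	fop	gc1s	gc2s	gc12
Bos grunniens	48.04	0.193	-0.004	0.416	0.4932	0.5961	0.54465
Bos taurus	53.82	0.129	-0.006	0.386	0.7471	0.576	0.66155
Macaca mulatta	52.31	0.157	0.006	0.413	0.4982	0.6751	0.58665
Mus musculus	55.09	0.163	0.034	0.416	0.6238	0.5439	0.58385
Oryctolagus cuniculus	43.1	0.29	0.193	0.539	0.565	0.491	0.528
Sus scrofa	44.62	0.261	0.17	0.524	0.5579	0.52	0.53895
Canis lupus familiaris	55.29	0.146	0.014	0.4	0.6706	0.5569	0.61375
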