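species	enc	cai	cbi	fop	gc1s	gc2s	gc12
Bos grunniens	44.44	0.256	0.24	0.558	0.6713	0.5295	0.6004
Bos taurus	42.48	0.291	0.249	0.566	0.6015	0.4955	0.5485
Macaca mulatta	44.99	0.252	0.191	0.53	0.5997	0.5045	0.5521
Mus musculus	56.96	0.16	0.042	0.419	0.6105	0.5448	0.57765
Oryctolagus cuniculus	54.05	0.154	0.011	0.419	0.5065	0.8191	0.6628
Sus scrofa	43.79	0.282	0.222	0.549	0.5958	0.4863	0.54105
Canis lupus familiaris	40.95	0.287	0.243	0.563	0.6025	0.4916	0.54705
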