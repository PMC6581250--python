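rsid	gene	effect_allele	other_allele	eaf	beta	ci_low	ci_high	se	n
rs3755967	GC	C	T	0.72	0.089	0.084	0.094	0.002551	79366
rs117913124	CYP2R1	G	A	0.975	0.21	0.19	0.23	0.010204	42274
rs10741657	CYP2R1	A	G	0.4	0.031	0.027	0.035	0.002041	79366
rs12785878	DHCR7	T	G	0.75	0.036	0.032	0.04	0.002041	79366
rs10745742	AMDHD1	T	C	0.41	0.017	0.013	0.021	0.002041	79366
rs8018720	SEC23A	G	C	0.27	0.017	0.012	0.022	0.002551	79366
rs17216707	CYP24A1	T	C	0.79	0.026	0.021	0.031	0.002551	79366
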