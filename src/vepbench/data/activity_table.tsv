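variant	genomic	clinvar	hgmd	gnomad_ac	gnomad_af	mean_rwt	p25	p75	luciferase_label	gelshift_label
p.D194Y	g.1220487G>T	P/LP	DM			-0.09	-0.24	0.08	LoF	LoF
p.G56W	g.1207078G>T					-0.08	-0.1	0	LoF	LoF
p.P179R	g.1220443C>G		DM			-0.01	-0.04	0.1	LoF	LoF
p.S193Y	g.1220485C>A					0.02	-0.02	0.15	LoF	LoF
p.S216F	g.1220629C>T	VUS				0.15	0.01	0.36	LoF	LoF
p.P221R	g.1220644C>G					0.19	0.04	0.37	LoF	LoF
p.F148S	g.1219391T>C					0.20	-0.03	0.44	LoF	LoF
p.G163R	g.1220394G>C	LP	DM			0.22	0.06	0.32	LoF	LoF
p.A241P	g.1220703G>C		DM			0.27	0.09	0.46	LoF	LoF
p.R297M	g.1221975G>T					0.32	0.17	0.43	LoF	LoF
p.H202R	g.1220587A>G	VUS		5	3.16e-06	0.34	0.19	0.49	LoF	WT-like
p.W308R	g.1222985T>C	VUS				0.38	0.19	0.52	LoF	LoF
p.G242V	g.1220707G>T		DM?			0.38	0.31	0.43	LoF	LoF
p.R297S	g.1221976G>T	P				0.41	0.32	0.49	LoF	LoF
p.G251C	g.1221228G>T					0.56	0.36	0.79	LoF	LoF
p.S31F	g.1207004C>T					0.69	0.56	0.89	WT-like	WT-like
p.P275L	g.1221301C>T	VUS				0.81	0.72	0.91	WT-like	WT-like
p.K84del	g.1207153_1207155delAAG	VUS		7	4.34e-06	0.90	0.61	1.09	WT-like	WT-like
p.R211Q	g.1220614G>A	VUS/LB		29	1.81e-05	1.00	0.79	1.18	WT-like	WT-like
p.Q112E	g.1218459C>G	VUS		2	1.24e-06	1.06	0.69	1.17	WT-like	WT-like
p.G155R	g.1219411G>A	VUS		3	1.90e-06	1.07	0.8	1.13	WT-like	WT-like
p.R104G	g.1218435A>G	VUS		6	3.72e-06	1.08	0.92	1.18	WT-like	WT-like
p.R409W	g.1226569C>T	VUS/LB	DM?	68	4.28e-05	1.11	0.91	1.18	WT-like	WT-like
p.A417S	g.1226593G>T	VUS		16	1.02e-05	1.29	0.86	1.66	WT-like	WT-like
p.A397S	g.1226533G>T	VUS/LB	DM?	30	1.87e-05	1.30	0.93	1.6	WT-like	WT-like
p.P280A	g.1221315C>G	VUS				1.47	1.39	1.68	WT-like	WT-like
p.F354L	g.1223125C>G	B/LB	DM?	8225	5.10e-03	1.51	0.93	1.88	WT-like	WT-like
p.K311N	g.1222996G>T					1.62	1.25	2.03	WT-like	WT-like
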