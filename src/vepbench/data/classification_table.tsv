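variant	clinvar	hgmd	gnomad_af	pop_code	pop_points	assay_result	func_code	func_points	revel	comp_code	comp_points	colocated	pm5_points	total	category	prior_definitive
p.G56W				PM2	1	LoF-LoF	PS3	2	0.932	PP3	4		0	7	LP	0
p.P179R		DM		PM2	1	LoF-LoF	PS3	2	0.939	PP3	4	P179Q|LP|0.94	1	8	LP	0
p.S193Y				PM2	1	LoF-LoF	PS3	2	0.871	PP3	2		0	5	VUS-high	0
p.S216F	VUS			PM2	1	LoF-LoF	PS3	2	0.954	PP3	4		0	7	LP	0
p.P221R				PM2	1	LoF-LoF	PS3	2	0.892	PP3	2		0	5	VUS-high	0
p.F148S				PM2	1	LoF-LoF	PS3	2	0.728	PP3	1		0	4	VUS-high	0
p.A241P		DM		PM2	1	LoF-LoF	PS3	2	0.782	PP3	2		0	5	VUS-high	0
p.R297M				PM2	1	LoF-LoF	PS3	2	0.936	PP3	4	R297S|P|0.94	2	9	LP	0
p.H202R	VUS		3.16e-06		0	LoF-WT		0	0.424		0		0	0	VUS-low	0
p.W308R	VUS			PM2	1	LoF-LoF	PS3	2	0.881	PP3	2	W308C|LP|0.73;W308L|LP|0.84	2	7	LP	0
p.G242V		DM?		PM2	1	LoF-LoF	PS3	2	0.97	PP3	4	G242R|P|0.97	2	9	LP	0
p.G251C				PM2	1	LoF-LoF	PS3	2	0.833	PP3	2		0	5	VUS-high	0
p.S31F				PM2	1	WT-WT	BS3	-2	0.8	PP3	2		0	1	VUS-low	0
p.P275L	VUS			PM2	1	WT-WT	BS3	-2	0.663	PP3	1		0	0	VUS-low	0
p.K84del	VUS		4.34e-06		0	WT-WT	BS3	-2			0		0	-2	LB	0
p.R211Q	VUS/LB		1.81e-05		0	WT-WT	BS3	-2	0.215	BP4	-1		0	-3	LB	0
p.Q112E	VUS		1.24e-06		0	WT-WT	BS3	-2	0.393		0		0	-2	LB	0
p.G155R	VUS		1.90e-06		0	WT-WT	BS3	-2	0.382		0		0	-2	LB	0
p.R104G	VUS		3.72e-06		0	WT-WT	BS3	-2	0.582		0		0	-2	LB	0
p.R409W	VUS/LB	DM?	4.28e-05		0	WT-WT	BS3	-2	0.238	BP4	-1		0	-3	LB	0
p.A417S	VUS		1.02e-05		0	WT-WT	BS3	-2	0.102	BP4	-2		0	-4	LB	0
p.A397S	VUS/LB	DM?	1.87e-05		0	WT-WT	BS3	-2	0.03	BP4	-2		0	-4	LB	0
p.P280A	VUS			PM2	1	WT-WT	BS3	-2	0.097	BP4	-2		0	-3	LB	0
p.K311N				PM2	1	WT-WT	BS3	-2	0.461		0		0	-1	LB	0
p.D194Y	P/LP	DM		PM2	1	LoF-LoF	PS3	2	0.929	PP3	2	D194H|P|0.94;D194V|P|0.94;D194E|P|0.84	4	9	LP	1
p.G163R	LP	DM		PM2	1	LoF-LoF	PS3	2	0.933	PP3	4	G163D|P|0.95	0	7	LP	1
p.R297S	P			PM2	1	LoF-LoF	PS3	2	0.936	PP3	4		0	7	LP	1
p.F354L	B/LB	DM?	5.10e-03	BS1	-4	WT-WT	BS3	-2	0.156	BP4	-2		0	-8	B	1
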