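factor_type	mirna	snp	p_adjusted	coefficient
clinical	age		NA	0.077
clinical	sex		NA	0.530
clinical	apoe4		NA	0.602
pair	MIMAT0019690	rs6721935	0.092	0.181
pair	MIMAT0015080	rs12616298	0.089	-0.170
pair	MIMAT0005582	rs12997752	0.038	-0.141
pair	MIMAT0027499	rs76232851	0.093	0.042
pair	MIMAT0019229	rs117574479	0.032	0.152
pair	MIMAT0019229	rs116868325	9.69e-9	0.058
pair	MIMAT0019045	rs3777118	1.10e-4	0.034
pair	MIMAT0021034	rs118073044	0.037	1.078
pair	MIMAT0000751	rs118073044	0.078	-3.163
pair	MIMAT0001630	rs118073044	0.020	1.654
pair	MIMAT0000086	rs117393460	0.078	0.260
pair	MIMAT0021033	rs72861163	0.037	0.337
pair	MIMAT0030997	rs9507595	0.086	-0.123
pair	MIMAT0027602	rs17682567	0.072	-0.050
pair	MIMAT0015080	rs117534907	0.006	-0.032
pair	MIMAT0023710	rs11855092	0.014	0.156
pair	MIMAT0016899	rs79726130	0.054	-0.436
pair	MIMAT0028122	rs79726130	0.049	0.465
pair	MIMAT0015080	rs35831886	1.97e-5	1.785
pair	MIMAT0019229	rs35831886	0.008	-1.688
pair	MIMAT0019045	rs117336092	0.031	-0.016
pair	MIMAT0019229	rs117099240	0.061	0.028
pair	MIMAT0032029	rs149944930	0.009	0.090
pair	MIMAT0027487	rs2830386	0.069	0.125
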