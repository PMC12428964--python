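precursor	product	enzyme_gene	silent
Cer	GlcCer	UGCG	0
GlcCer	LacCer	B4GALT5/6	0
LacCer	GM3	ST3GAL5	0
LacCer	GA2	B4GALNT1	1
GM3	GM2	B4GALNT1	0
GM3	GD3	ST8SIA1	0
GM2	GM1a	B3GALT4	0
GM1a	GD1a	ST3GAL2/3	0
GD1a	GT1a	ST8SIA5	1
GD3	GD2	B4GALNT1	0
GD3	GT3	ST8SIA3	1
GD2	GD1b	B3GALT4	0
GD1b	GT1b	ST3GAL2/3	0
GT1b	GQ1b	ST8SIA5	1
GA2	GA1	B3GALT4	1
GA1	GM1b	ST3GAL2/3	1
GM1b	GD1alpha	ST6GALNAC5	1
GM1b	GD1c	ST8SIAx	1
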