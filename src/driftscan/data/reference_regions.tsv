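id	chrom	start_mb	end_mb	length_kb	tests	category	n_genes	gene_names
SSC1:16	1	16.33	16.36	34	hapFLK	div	2	KATNA1,GINM1
SSC1:95	1	95.44	95.63	186	LWS	conv	3
SSC1:110	1	110.37	111.69	1328	hapFLK	div	6
SSC1:230	1	230.43	230.44	6	LWD	LWD	1	GNA14
SSC1:238	1	238.38	239.9	1518	LWD	conv(LWD)	20
SSC1:253	1	253.31	253.45	134	LWD	LWD	3
SSC2:1	2	1.22	1.53	305	LWD,LWS	conv	12
SSC2:45	2	45.74	45.76	20	LWS	conv(LWS)	2	PTH
SSC2:145	2	145.18	145.18	0	LWD	conv(LWD)	0
SSC2:151	2	151.01	151.38	371	hapFLK	div	10
SSC3:3	3	3.85	3.86	6	LWD	conv(LWD)	1	SLC29A4
SSC3:124	3	124.83	124.84	1	LWS	LWS	0
SSC4:18	4	18.01	18.03	17	hapFLK	div	0
SSC4:54	4	54.79	54.8	5	LWS	conv(LWS)	1	SNX16
SSC5:94	5	94.16	94.17	18	hapFLK	div	0
SSC6:13	6	13.87	13.87	1	LWS	LWS	1
SSC6:72	6	72.3	72.31	15	LWS	conv(LWS)	2	VPS13D,RF00156
SSC7:18	7	18.6	18.62	11	hapFLK	div	0
SSC7:85	7	85.68	85.69	1	LWS	LWS	1
SSC8:80	8	80.67	80.75	72	hapFLK	div	1	ARHGAP10
SSC8:124	8	124.62	124.62	0	hapFLK	LWS	1	BMPR1B
SSC9:19	9	19.37	19.9	538	LWS	conv(LWS)	13
SSC9:96	9	96.7	98.42	1721	LWD	conv(LWD)	5
SSC9:101	9	101.3	104.51	3206	LWD	conv	26
SSC9:107	9	107.83	108.62	784	LWS	conv(LWS)	8
SSC10:23	10	23.7	23.7	2	LWS	conv(LWS)	1	PKP1
SSC10:62	10	62.92	62.93	12	LWS	conv(LWS)	0
SSC11:7	11	7.66	7.79	130	LWD,hapFLK	LWD	3	HSPH1,B3GLCT
SSC11:51	11	51.15	51.16	5	LWD	LWD	0
SSC13:99	13	99.09	99.09	3	LWS	conv	0
SSC13:109	13	109.1	110.15	1046	LWS	conv	9
SSC13:113	13	113.97	114.2	233	LWS	conv(LWS)	1	NAALADL2
SSC13:191	13	191.52	191.54	14	hapFLK	div	0
SSC16:69	16	69.96	70.9	941	LWD	LWD	6
SSC17:1	17	1.86	4.02	2153	LWD	LWD	8
SSC17:43	17	43.48	43.91	434	LWS	conv(LWS)	3
SSC17:60	17	60.33	60.79	466	hapFLK	div	0
SSC18:10	18	10.54	10.56	20	hapFLK	div	1	ZC3HAV1
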