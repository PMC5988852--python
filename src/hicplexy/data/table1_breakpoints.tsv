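translocation_id	partner_id	chrom	start	stop	genes	single_fragment	wgs_confirmed
t1	t1_1p35.3	chr1	28238215	28248287	RPA2	1	0
t1	t1_4p16.3	chr4	4050000	4150000	BC042823	0	0
t2	t2_1q21.3	chr1	150769818	150781274	CTSK	1	0
t2	t2_16p13.13	chr16	11004475	11019710	CIITA	1	1
t3	t3_2q14.2	chr2	120270564	120285427	SCTR	1	1
t3	t3_6q16.1	chr6	98127299	98143928	LOC101927314	1	1
t4	t4_2q22.1	chr2	137227625	137228172	—	1	1
t4	t4_6q21	chr6	114395987	114399043	HDAC2-AS2	1	1
t5	t5_11q14.3	chr11	88350000	88450000	GRM5	0	1
t5	t5_2p22.3	chr2	32260000	32360000	Several genes	0	1
t6	t6_11q14.3	chr11	88350000	88450000	GRM5	0	1
t6	t6_2p22.3	chr2	32230000	32330000	Several genes	0	1
t7	t7_3q13.2	chr3	112240000	112340000	Several genes	0	0
t7	t7_6q21	chr6	106400000	106500000	—	0	1
t8	t8_3q13.2	chr3	113435703	113437137	NAA50	1	0
t8	t8_17q11.2	chr17	28807394	28808819	GOSR1	1	0
t9	t9_3q24	chr3	143214724	143222670	SLC9A9	1	1
t9	t9_Xp21.1	chrX	36597000	36600264	—	1	1
t10	t10_16p13.13	chr16	11954332	11955153	—	1	0
t10	t10_4p16.3	chr4	3315595	3322490	RGS12	1	0
t11	t11_5p13.2	chr5	37046678	37051545	NIPBL	1	1
t11	t11_8p23.1	chr8	10977335	10981039	XKR6	1	1
t12	t12_10q23.31	chr10	91799056	91801084	—	1	1
t12	t12_5q13.2	chr5	37046678	37051545	NIPBL	1	1
t13	t13_17q25.1	chr17	70991114	71006897	SLC39A11	1	0
t13	t13_5q31.3	chr5	143656972	143667413	KCTD16	1	0
t14	t14_5q35.2	chr5	176114621	176120288	—	1	1
t14	t14_17q24.3	chr17	70537801	70539618	LINC00673	1	1
t15	t15_6q24.2	chr6	143380000	143480000	AIG1	0	1
t15	t15_17q11.2	chr17	28770000	28870000	CPD;GOSR1	0	1
t16	t16_10q22.1	chr10	71038330	71050820	HK1	1	0
t16	t16_7q31.33	chr7	126890674	126899921	GRM8	1	0
t17	t17_10q23.33	chr10	95298787	95314132	—	1	1
t17	t17_8p23.1	chr8	10977335	10981039	XKR6	1	1
t18	t18_12p12.2	chr12	20833396	20843983	PDE3A	1	0
t18	t18_10p14	chr10	7970549	7976904	TAF3	1	0
t19	t19_13q12.3	chr13	31132320	31134497	HMGB1	1	1
t19	t19_11p15.5	chr11	1444072	1449221	BRSK2	1	1
t20	t20_12p12.3	chr12	18675961	18680225	PIK3C2G	1	0
t20	t20_Xq28	chrX	147292149	147300244	—	1	0
t21	t21_17q25.3	chr17	75511241	75516019	—	1	1
t21	t21_19p13.3	chr19	3737154	3750893	TJP3	1	0
t22	t22_17q24.3	chr17	69185554	69188239	CASC17	1	0
t22	t22_9q21.13	chr9	74350000	74600000	Several genes	0	0
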