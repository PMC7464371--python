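sample_id	dataset_id	platform_id	sex	pool	age	scale
GSM226880	GSE8954	GPL201	M	A	40.2 ± 14.2	linear
GSM226881	GSE8954	GPL201	M	A	40.2 ± 14.2	linear
GSM226882	GSE8954	GPL201	F	B (D)	40.2 ± 14.2	linear
GSM226883	GSE8954	GPL201	F	B (D)	40.2 ± 14.2	linear
GSM311246	GSE12399	GPL201	M	A	52	linear
GSM311250	GSE12399	GPL201	F	B (C)	42	linear
GSM455150	GSE18201	GPL201	F	B (C)	42	linear
GSM455151	GSE18201	GPL201	M	A	49	linear
GSM455152	GSE18201	GPL201	F	B (C)	51	linear
GSM493884	GSE19773	GPL7363	F	B (D)	(18–39)	linear
GSM493885	GSE19773	GPL7363	F	B (D)	(18–39)	linear
GSM602158	GSE24433	GPL571	F	B (D)	Adult	linear
GSM916113	GSE37324	GPL6244	F	B (C)	69	linear
GSM916114	GSE37324	GPL6244	F	B (C)	69	linear
GSM916116	GSE37324	GPL6244	F	B (C)	69	linear
GSM916117	GSE37324	GPL6244	M	A	71	linear
GSM916119	GSE37324	GPL6244	M	A	71	linear
GSM916123	GSE37324	GPL6244	M	A	71	linear
GSM916124	GSE37324	GPL6244	F	B (C)	62	linear
GSM916128	GSE37324	GPL6244	F	B (C)	62	linear
GSM916129	GSE37324	GPL6244	M	A	53	linear
GSM916130	GSE37324	GPL6244	F	B (C)	62	linear
GSM916132	GSE37324	GPL6244	M	A	56	linear
GSM916135	GSE37324	GPL6244	M	A	53	linear
GSM916136	GSE37324	GPL6244	M	A	53	linear
GSM1173058	GSE48220	GPL6480	F	B (D)	39	linear
GSM1173059	GSE48220	GPL6480	F	B (D)	31	linear
GSM1173060	GSE48220	GPL6480	F	B (D)	35	linear
GSM1173061	GSE48220	GPL6480	F	B (D)	32	linear
GSM1173062	GSE48220	GPL6480	F	B (D)	29	linear
GSM1173063	GSE48220	GPL6480	F	B (D)	37	linear
GSM1184376	GSE48774	GPL6884	F	B (D)	(24–40)	linear
GSM1184377	GSE48774	GPL6884	F	B (D)	(24–40)	linear
GSM1184378	GSE48774	GPL6884	F	B (D)	(24–40)	linear
GSM1384338	GSE57538	GPL13158	F	B (D)	(36–45)	linear
GSM1384339	GSE57538	GPL13158	F	B (D)	(36–45)	linear
GSM1384340	GSE57538	GPL13158	F	B (D)	(36–45)	linear
GSM2047165	GSE77272	GPL10558	M	A	31	linear
GSM2047164	GSE77272	GPL10558	F	B (D)	56	linear
GSM2047166	GSE77272	GPL10558	F	B (D)	19	linear
GSM2047167	GSE77272	GPL10558	F	B (D)	57	linear
GSM2595136	GSE98421	GPL570	F	B (D)	30	linear
GSM2595137	GSE98421	GPL570	F	B (D)	19	linear
GSM2595138	GSE98421	GPL570	F	B (D)	29	linear
GSM2595139	GSE98421	GPL570	F	B (D)	33	linear
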