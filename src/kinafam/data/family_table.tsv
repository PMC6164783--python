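name	gene_id	chromosome	aa_length	cds_length_bp	mw_kda	pi	exon_count	tloop	location
AcMAPK1	Achn005721	15	374	1125	42.93	6.44	6	TEY	Chloroplast
AcMAPK2	Achn025711	11	379	1140	43.65	7.12	3	TEY	Nuclear, Cytoplasm
AcMAPK3	Achn060571	28	340	1023	38.99	4.89	6	TEY	Cytoplasm
AcMAPK4	Achn074341	Un	376	1131	43.36	6.51	6	TEY	Cytoplasm
AcMAPK5	Achn082251	23	344	1035	39.74	5.41	6	TEY	Cytoplasm
AcMAPK6	Achn098501	20	1056	3171	119.46	9.14	29	TEY	Cytoplasm
AcMAPK7	Achn131961	Un	371	1116	42.56	6.89	2	TEY	Cytoplasm
AcMAPK8	Achn132381	25	434	1305	49.42	7.39	7	TEY	Cytoplasm
AcMAPK9	Achn135551	1	336	1011	39.11	7.90	3	TEY	Peroxisome
AcMAPK10	Achn146591	13	601	1806	67.76	9.17	9	TDY	Chloroplast
AcMAPK11	Achn195331	13	425	1278	48.30	4.52	8	TEY	Vacuolar
AcMAPK12	Achn209161	1	340	1023	38.82	6.25	5	TEY	Cytoplasm
AcMAPK13	Achn228801	25	451	1356	51.08	9.82	16	TEY	Cytoplasm, Nuclear
AcMAPK14	Achn237151	29	862	2589	97.02	9.25	10	TDY	Nuclear, Chloroplast
AcMAPK15	Achn248791	Un	475	1428	54.89	5.15	7	TEY	Cytoplasm
AcMAPK16	Achn252431	2	403	1212	46.22	5.69	6	TEY	Cytoplasm
AcMAPK17	Achn296271	1	702	2109	79.02	9.03	11	TDY	Chloroplast
AcMAPK18	Achn377281	15	409	1230	46.34	5.40	16	TDY	Nuclear
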