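locus	snp_id	position	location	genes	pbc_p	pbc_or	psc_p	psc_or	minor_allele	maf	replication_panel
1p32	rs4927257	56046320	prom.	.	0.033	0.83	0.026	0.72	A	0.439	yes
2p25.3	rs1965732	3709108	intron	ALLC	0.028	1.24	0.029	1.41	G	0.266	no
5q34	rs9686714	167853274	intron	WWC1	0.048	0.68	7.7E-4	0.195	C	0.066	no
6p21	rs2187668	32605884	intron	HLA-DQA1	0.021	0.73	1.53E-7	2.47	T	0.128	yes
6p21	rs9272346	32604372	prom.	HLA-DQA1	0.0067	0.79	0.025	1.37	G	0.422	yes
6p21	rs7775228	32658079	inter.	LOC100294145, C4B_2	7.94E-9	1.84	0.00171	0.46	C	0.146	no
6p21	rs3213489	32724305	intron	HLA-DQB2	8.37E-9	0.60	0.00155	1.56	T	0.416	no
6p21	rs1799908	33144243	intron	COL11A2	0.032	1.21	0.0045	0.63	A	0.405	no
6p21	rs7454108	32681483	inter.	LOC100294145, C4B_2	0.0090	1.43	0.00130	0.326	C	0.086	no
9q34.3	rs10119096	139801932	intron	TRAF2	0.00087	0.70	0.041	0.70	T	0.263	no
10q26.11	rs17098094	120592334	inter.	MIR4681, CACUL1	0.0174	0.81	0.032	0.73	G	0.394	yes
1p31.3	rs10489626	67793171	intron	IL12RB2	2.11E-5	1.59	.	.	G	0.179	no
1p31.3	rs3790567	67822377	intron	IL12RB2	8.4E-4	1.37	.	.	A	0.242	no
1q32.1	rs3024505	206939904	inter.	IL24, CTSE	0.047	1.25	.	.	A	0.158	yes
2q31.1	rs2287619	169836730	intron	ABCB11	0.0079	1.50	.	.	C	0.076	no
1q24.3	rs12118836	171256038	inter.	MIR3120, MIR1295A	0.0081	1.37	.	.	A	0.145	no
3q13	rs28413019	109890863	inter.	PVRL3-AS1, DPPA2	0.022	1.25	.	.	G	0.237	yes
3q13	rs1491590	70657915	inter.	MIR1284, MITF	0.0021	1.34	.	.	G	0.251	yes
4p15.1	rs13126571	27725689	inter.	TBC1D19	0.031	1.24	.	.	A	0.230	no
4p14	rs3114381	40533297	intron	RBM47	0.0123	1.28	.	.	T	0.232	no
4q26	rs979961	117850456	inter.	TRAM1L1, MIR1973	0.0062	1.39	.	.	C	0.131	no
6p21	rs9268979	32435044	inter.	LOC100294145, C4B_2	6.73E-6	0.68	.	.	T	0.471	no
6p21	rs3128927	33074288	inter.	MIR1275, LOC100294145	2.16E-5	1.50	.	.	T	0.240	no
6q27	rs4710185	167522386	intron	CCR6	0.020	1.23	.	.	A	0.358	no
6q27	rs9459874	167504127	intron	CCR6	0.0040	1.29	.	.	T	0.425	no
6q27	rs975822	167516458	intron	CCR6	0.0042	1.29	.	.	T	0.459	yes
7q32.1	rs10488631	128594183	inter.	SMKR1, LOC100130705	0.0023	1.43	.	.	C	0.132	no
7p14.3	rs965571	33622588	intron	BBS9	7.0E-4	1.43	.	.	C	0.207	no
11q12.3	rs35730843	62527634	prom.	POLR2G	1.21E-5	0.393	.	.	C	0.070	no
11p15.3	rs12786216	11275192	inter.	MIR4299, MRVI1-AS1	0.0076	0.77	.	.	C	0.299	no
11q23.3	rs11217040	118680648	inter.	LOC100131626	9.22E-5	0.66	.	.	A	0.246	no
11q24.3	rs73022813	130704378	inter.	SNX19, ADAMTS8	0.043	1.24	.	.	A	0.176	yes
12p13.31	rs7975557	9853697	inter.	KLRF2, MIR1244-1	0.042	1.54	.	.	T	0.035	yes
14q21.1	rs10083358	39001998	inter.	LOC100288846, MIPOL1	0.0026	1.34	.	.	G	0.252	yes
16p12.3	rs8055224	20285401	inter.	ERI2, IQCK	0.0077	0.54	.	.	G	0.050	yes
16q23.3	rs8049648	83217488	intron	CDH13	0.00175	1.68	.	.	C	0.061	no
19q13.33	rs3745516	50926742	intron	SPIB	7E-05	1.45	.	.	A	0.254	yes
21q22.11	rs7279062	32074387	inter.	KRTAP21-3, KRTAP25-1	0.0110	0.80	.	.	T	0.476	yes
17q12	rs9303277	37976469	intron	IKZF3	0.0051	1.27	.	.	T	0.478	yes
3q22.1	rs11917172	132166266	coding	DNAJC13	.	.	0.0122	0.53	G	0.138	no
4p16.1	rs7686718	10171487	inter.	CLNK, USP17L10	.	.	0.00161	1.63	C	0.261	no
6q12	rs13191240	69675459	intron	ADGRB3	.	.	0.0095	0.2	C	0.04	no
5p15.31	rs6869702	6401135	inter.	MIR4278, ICE1	.	.	0.047	0.74	G	0.409	no
5q22.2	rs1554624	111655382	intron	EPB41L4A	.	.	0.0126	0.55	G	0.154	no
5q34	rs3822659	167858372	coding	WWC1	.	.	0.0051	0.24	TG	0.053	no
6p21	rs3130484	31715882	intron	MSH5-SAPCD1	.	.	5.12E-11	3.23	C	0.101	yes
6p21	rs1264377	30764907	inter.	PSORS1C3, MIR877	.	.	8.02E-8	2.39	A	0.159	no
6p21	rs2524163	31259579	intron	HLA-B	.	.	5.94E-7	2.02	C	0.429	no
6p21	rs3130626	31598489	intron	PRRC2A	.	.	1.5E-6	2.10	G	0.207	no
6p21	rs419788	31928799	intron	SKIV2L	.	.	1.21E-6	2.03	T	0.250	no
6p22.1	rs3815081	30114074	intron	TRIM40	.	.	0.0141	0.59	G	0.169	no
6p22.1	rs1936365	28268452	intron	PGBD1	.	.	0.0034	1.72	C	0.128	no
11q24.3	rs34708188	128223560	inter.	SENCR	.	.	0.0057	2.27	T	0.038	no
7q35	rs954072	144757945	inter.	CTAGE4	.	.	0.0069	0.66	C	0.406	no
8q21.13	rs1380634	80237893	inter.	MIR5708, LOC101241902	.	.	0.001011	1.70	G	0.241	no
15q21.3	rs11853454	54169638	inter.	UNC13C, WDR72	.	.	0.040	1.39	A	0.218	yes
17p13.2	rs238224	4863410	intron	SPAG7	.	.	0.0174	0.57	A	0.146	no
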