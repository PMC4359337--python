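association_id	probe_set	gene_symbol	gene_location	snp_id	risk_allele	snp_locus
1	209716_at	CSF1	1p13	rs10896449	G	11q13
2	204175_at	ZNF593	1p36	rs10896449	G	11q13
3	204197_s_at	RUNX3	1p36	rs10896449	G	11q13
4	202546_at	VAMP8	2p11-p12	rs10896449	G	11q13
5	205174_s_at	QPCT	2p22	rs10896449	G	11q13
6	218864_at	TNS1	2q35-q36	rs10896449	G	11q13
7	226766_at	ROBO2	3p12	rs10896449	G	11q13
8	219551_at	EAF2	3q13	rs10896449	G	11q13
9	232099_at	PCDHB16	5q31	rs10896449	G	11q13
10	205100_at	GFPT2	5q34-q35	rs10896449	G	11q13
11	208583_x_at	HIST1H2AJ	6p22	rs10896449	G	11q13
12	223475_at	CRISPLD1	8q21	rs10896449	G	11q13
13	204501_at	NOV	8q24	rs10896449	G	11q13
14	205041_s_at	ORM1 /// ORM2	9q32	rs10896449	G	11q13
15	205127_at	PTGS1	9q32-q33	rs10896449	G	11q13
16	213004_at	ANGPTL2	9q34	rs10896449	G	11q13
17	203666_at	CXCL12	10q11	rs10896449	G	11q13
18	204396_s_at	GRK5	10q26	rs10896449	G	11q13
19	203835_at	LRRC32	11q13-q14	rs10896449	G	11q13
20	211964_at	COL4A2	13q34	rs10896449	G	11q13
21	201562_s_at	SORD	15q15	rs10896449	G	11q13
22	203151_at	MAP1A	15q15	rs10896449	G	11q13
23	214297_at	CSPG4	15q24	rs10896449	G	11q13
24	224476_s_at	MESP1	15q26	rs10896449	G	11q13
25	229730_at	SMTNL2	17p13	rs10896449	G	11q13
26	218980_at	FHOD3	18q12	rs10896449	G	11q13
27	37996_s_at	DMPK	19q13	rs10896449	G	11q13
28	222106_at	PRND	20p13	rs10896449	G	11q13
29	205439_at	GSTT2	22q11	rs10896449	G	11q13
30	201787_at	FBLN1	22q13	rs10896449	G	11q13
31	220663_at	IL1RAPL1	Xp21-p22	rs10896449	G	11q13
32	204584_at	L1CAM	Xq28	rs10896449	G	11q13
33	238079_at	TPM3	1q21	rs1859962	G	17q24
34	206307_s_at	FOXD1	5q12-q13	rs1859962	G	17q24
35	203438_at	STC2	5q35	rs1859962	G	17q24
36	205040_at	ORM1	9q32	rs1859962	G	17q24
37	206529_x_at	SLC26A4	7q31	rs401681	C	5p15
38	204846_at	CP	3q23-q25	rs401681	C	5p15
39	203021_at	SLPI	20q12	rs401681	C	5p15
40	206307_s_at	FOXD1	5q12-q13	rs9623117	C	22q13
41	220120_s_at	EPB41L4A	5q21	rs9623117	C	22q13
42	228256_s_at	EPB41L4A	5q21	rs9623117	C	22q13
43	214676_x_at	MUC3A	7q22	rs9623117	C	22q13
44	211734_s_at	FCER1A	1q23	rs12621278	G	2q31
45	205132_at	ACTC1	15q14	rs1465618	A	2p21
46	210452_x_at	CYP4F2	19p13	rs620861	C	8q24
47	223775_at	HHIP	4q28-q32	rs6983267	G	8q24
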