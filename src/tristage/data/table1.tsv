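profile	pattern	rank	gene	hgnc_id	mcc_scores	go_terms	pathways	drmp_p	hub_gene_sets
11	0,1,1	1	HDAC2	HGNC:4853	62,92	42	6	>0.05	EvCup,MvCup
11	0,1,1	2	EP300	HGNC:3373	47,37	70	5	>0.05	EvCup,MvCup
11	0,1,1	3	RAC1	HGNC:9801	35,35	51	41	>0.05	EvCup,MvCup
11	0,1,1	4	CRK	HGNC:2362	34,38	19	6	>0.05	EvCup,MvCup
11	0,1,1	5	TBP	HGNC:11588	28,28	18	6	0.046	EvCup,MvCup
11	0,1,1	6	SMAD1	HGNC:6767	24,28	34	23	0.009	EvCup,MvCup
11	0,1,1	7	ABI1	HGNC:11320	23	74	0	>0.05	EvCup
11	0,1,1	8	SMAD4	HGNC:6770	23	25	78	0.0001	EvCup
11	0,1,1	9	TGFBR1	HGNC:11772	22,22	57	8	>0.05	EvCup,MvCup
11	0,1,1	10	CEBPA	HGNC:1833	21,21	31	5	>0.05	EvCup,MvCup
11	0,1,1	11	CDC42	HGNC:1736	21	32	5	>0.05	MvCup
11	0,1,1	12	H3F3A	HGNC:4764	18,18	18	4	>0.05	EvCup,MvCup
11	0,1,1	13	SMARCB1	HGNC:11103	17,17	27	7	>0.05	EvCup,MvCup
11	0,1,1	14	TNFRSF1A	HGNC:11916	16	21	2	>0.05	EvCup
11	0,1,1	15	PDPK1	HGNC:8816	16,16	49	9	0.024	EvCup,MvCup
11	0,1,1	16	MAP2K1	HGNC:6840	14	24	6	>0.05	EvCup
11	0,1,1	17	PFN1	HGNC:8881	13	14	4	>0.05	EvCup
11	0,1,1	18	NFKB1	HGNC:7794	12,11	28	12	>0.05	EvCup,MvCup
11	0,1,1	19	CASP7	HGNC:1508	12	0	0	>0.05	EvCup
11	0,1,1	20	PLA2G4A	HGNC:9035	11	16	10	>0.05	EvCup
11	0,1,1	21	SH3GL2	HGNC:10831	10,10	8	0	>0.05	EvCup,MvCup
11	0,1,1	22	ATF4	HGNC:786	10	9	9	>0.05	EvCup
11	0,1,1	23	APH1B	HGNC:24080	10,10	7	0	>0.05	EvCup,MvCup
11	0,1,1	24	PKNOX1	HGNC:9022	10	0	0	>0.05	EvCup
14	0,2,1	1	STK38	HGNC:17847	50,49,50	28	10	>0.05	EvCup,MvCup,EvMdown
14	0,2,1	2	CDK2	HGNC:1771	41,58	13	7	>0.05	EvCup,EvMdown
14	0,2,1	3	KIT	HGNC:6342	32	26	26	>0.05	EvMdown
14	0,2,1	4	LBR	HGNC:6518	29,29,29	10	20	>0.05	EvCup,MvCup,EvMdown
14	0,2,1	5	DAB1	HGNC:2661	26	17	4	>0.05	EvMdown
14	0,2,1	6	CAMK2A	HGNC:1460	22,26,21	32	7	0.0051	EvCup,MvCup,EvMdown
14	0,2,1	7	ACTG1	HGNC:144	17,17	11	4	>0.05	EvCup,MvCup
14	0,2,1	8	HDAC4	HGNC:14063	17	23	12	>0.05	EvMdown
14	0,2,1	9	ITGB1	HGNC:6153	16,16	49	7	>0.05	EvCup,MvCup
14	0,2,1	10	NR3C1	HGNC:7978	15,17	41	3	>0.05	EvCup,MvCup
14	0,2,1	11	LEPR	HGNC:6554	15	7	3	>0.05	EvMdown
14	0,2,1	12	CCND2	HGNC:1583	14	8	8	>0.05	EvMdown
14	0,2,1	13	MTA1	HGNC:7410	14,15	7	1	>0.05	EvCup,EvMdown
14	0,2,1	14	SALL4	HGNC:15924	14,60	13	1	>0.05	EvCup,EvMdown
14	0,2,1	15	PFN2	HGNC:8882	13	0	0	>0.05	EvCup
14	0,2,1	16	ERBB2	HGNC:3430	12	40	0	>0.05	MvCup
14	0,2,1	17	ATXN3	HGNC:7106	11,11	19	1	0.0273	EvCup,MvCup
14	0,2,1	18	NDEL1	HGNC:17620	11	19	9	>0.05	EvMdown
14	0,2,1	19	CAV1	HGNC:1527	11	38	5	>0.05	EvMdown
14	0,2,1	20	CBLB	HGNC:1542	10	8	8	>0.05	EvMdown
4	0,-1,-1	1	CYLD	HGNC:2584	26,50	26	8	>0.05	EvCdown,MvCdown
4	0,-1,-1	2	GRIN2B	HGNC:4586	23	10	8	>0.05	MvCdown
4	0,-1,-1	3	DAXX	HGNC:2681	14	5	7	>0.05	MvCdown
4	0,-1,-1	4	CDH2	HGNC:1759	11	10	6	0.0011	MvCdown
15	0,1,2	1	EWSR1	HGNC:3508	49,49	14	11	>0.05	MvCup,EvMup
15	0,1,2	2	SMC3	HGNC:2468	26	11	12	>0.05	EvCup
15	0,1,2	3	HIST1H4C	HGNC:4787	14	0	2	>0.05	EvCup
15	0,1,2	4	LIN7C	HGNC:17789	12	26	0	>0.05	EvCup
15	0,1,2	5	TET2	HGNC:25941	10	30	0	>0.05	MvCup
12	0,2,2	1	PPP1CC	HGNC:9283	52,52	17	38	>0.05	EvCup,MvCup
12	0,2,2	2	PCNA	HGNC:8729	23	12	24	>0.05	EvCup
12	0,2,2	3	ELOC	HGNC:11617	16	8	14	>0.05	EvCup
0	0,-1,-2	1	RYR1	HGNC:10483	19	9	10	>0.05	EvCdown
0	0,-1,-2	2	NOTCH1	HGNC:7881	15,15,15	59	8	>0.05	EvCdown,MvCdown,EvMdown
1	0,-2,-1	1	PRNP	HGNC:9449	47,47	31	7	>0.05	MvCdown,EvMup
1	0,-2,-1	2	PPP2CA	HGNC:9299	19,20	19	4	>0.05	MvCdown,EvMup
1	0,-2,-1	3	APC	HGNC:583	15	18	2	>0.05	MvCdown
1	0,-2,-1	4	HDAC6	HGNC:14064	14,14	28	6	>0.05	EvCdown,MvCdown
1	0,-2,-1	5	USP8	HGNC:12631	12	5	10	>0.05	EvMup
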