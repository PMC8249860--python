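no	sample_id	peptide	protein	mutation_aa	hla_allele	affinity_nM	rank_pct	validated_source	drugs
1	T9	LHGGWTTKM	PIK3CA	H1047L	HLA-B15:18	490.2144	0.1622	TSNAdb-CESC	BAY 80-6946
2	T5	LRMVRGTQVY	ERBB3	V104M	HLA-C07:02	301.045	0.0906	TSNAdb-CESC	Trastuzumab
3	T5	LRMVRGTQV	ERBB3	V104M	HLA-C07:02	192.3883	0.1237	TSNAdb-CESC	Elisidepsin
4	T5	RMVRGTQVY	ERBB3	V104M	HLA-B15:18	265.2144	0.0758	TSNAdb-CESC	EZN-3920
5	T1	MIDSKTAEM	DSG3	I444M	HLA-B67:*	158.4915	0.6763	TSNAdb-CESC	Literature-reported Target
6	T6	ALPASERGWK	C3orf70	S6L	HLA-B40:01	370.518	0.9879	TSNAdb-CESC	/
7	T5	SYTHIQYLF	SH2D3C	Q129R	HLA-A34:01	283.251	0.1863	IEDB	/
8	T2	LTFRDVAIEF	ZNF468	Q19E	HLA-C12:03	358.2076	1.2376	IEDB	/
9	CC-X004	LHVLMGHVAAV	FBXW7	R505G	HLA-A02:01	25.157	0.3445	TSNAdb-CESC	Literature-reported Target
10	CC-X004	HVLMGHVAAV	FBXW7	R505G	HLA-A02:01	26.1568	0.3571
11	CC-X004	VLMGHVAAV	FBXW7	R505G	HLA-A02:01	82.6567	0.9305
12	CC-X004	VLMGHVAAV	FBXW7	R505G	HLA-A02:01	3.1125	0.0094
13	T5	HTKDIFNVK	ADAM29	R399H	HLA-A34:01	63.2156	0.0205	CTAs	/
14	T5	MASFRKLML	LUZP4	T8M	HLA-B67:01	418.5688	0.615	CTAs	/
15	T5	FPNLPHLSF	MAGEC3	R9H	HLA-C07:02	468.0406	0.1553	CTAs	/
16	T5	FPNLPHLSF	MAGEC3	R9H	HLA-B67:01	11.2897	0.0146	CTAs	/
17	T5	MPLFPNLPHL	MAGEC3	R9H	HLA-B15:18	10.6791	0.013	CTAs	/
18	T5	SPIEIGLFI	OTOA	T195M	HLA-A34:01	52.8519	0.1197	CTAs	/
19	T5	SRHNKALKL	OTOA	T195M	HLA-C07:02	75.4928	0.0382	CTAs	/
20	T5	FPKLTKNML	PRSS55	A236V	HLA-B15:18	32.3202	0.0684	CTAs	/
21	T5	MFPKLTKNM	PRSS55	A236V	HLA-B15:18	374.1032	0.2469	CTAs	/
22	T5	MFPKLTKNML	PRSS55	A236V	HLA-A34:01	442.851	0.6403	CTAs	/
23	T1	IPALSARDL	SAGE1	M193L	HLA-A26:01	78.8728	0.1714	CTAs	/
24	T1	LINMAATPI	SAGE1	M193L	HLA-B15:18	228.4982	0.9079	CTAs	/
25	T1	MAATPIPAL	SAGE1	M193L	HLA-B15:18	37.04	0.0829	CTAs	/
26	T1	MAATPIPAL	SAGE1	M193L	HLA-B15:18	12.4152	0.0368	CTAs	/
27	T1	SARDLYATV	SAGE1	M193L	HLA-B15:18	32.9825	0.1358	CTAs	/
28	T1	TPIPALSARDL	SAGE1	M193L	HLA-A26:01	103.2219	0.2134	CTAs	/
29	T6	IVKNDLIAK	SPAG9	E283K	HLA-B40:01	147.4087	0.5079	CTAs	/
30	T6	KVDKLTCEK	SPAG9	E283K	HLA-A03:01	261.5526	0.7731	CTAs	/
31	CC-X004	SVMKLCLIMV	AKAP4	A712V	HLA-A02:01	91.7051	1.0019	CTAs	/
32	CC-H024	TPAMEGAVA	ARX	V508M	HLA-B35:01	440.195	0.8127	CTAs	Cetuximab PEGylated IFN beta 1-a HGH-CTP
33	CC-H024	LLRQPTPAM	ARX	V508M	HLA-C03:03	135.4831	0.4402
34	CC-H024	MALLLVLFLV	CRISP2	P5L	HLA-A02:01	223.9094	1.7662	CTAs	/
35	CC-H024	LLLVLFLVTV	CRISP2	P5L	HLA-A02:01	184.453	1.5646	CTAs	/
36	CC-H024	ALLLVLFLV	CRISP2	P5L	HLA-A02:01	47.3197	0.6001	CTAs	/
37	CC-H024	LLVLFLVTV	CRISP2	P5L	HLA-A02:01	131.0198	1.2594	CTAs	/
38	CC-H024	VLFLVTVLL	CRISP2	P5L	HLA-A02:01	106.6147	1.0997	CTAs	/
39	CC-H024	FLVTVLLPS	CRISP2	P5L	HLA-A02:01	32.8486	0.4379	CTAs	/
40	CC-H024	MALLLVLFL	CRISP2	P5L	HLA-C03:03	243.1628	0.6375	CTAs	/
41	CC-H024	LVLFLVTVL	CRISP2	P5L	HLA-C03:03	461.3886	0.9529	CTAs	/
42	CC-H024	KVWVQGHYL	MAGEC2	R287Q	HLA-A02:01	224.0936	1.7671	CTAs	CV-9201
43	CC-H024	WVQGHYLEY	MAGEC2	R287Q	HLA-B35:01	32.875	0.1302	CTAs	/
44	CC-H024	EVPHSSPPY	MAGEC2	R287Q	HLA-B35:01	261.5695	0.591	CTAs	/
45	CC-H024	VPHSSPPYY	MAGEC2	R287Q	HLA-B35:01	20.2	0.0829	CTAs	/
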