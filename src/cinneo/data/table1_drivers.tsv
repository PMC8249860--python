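sample_id	gene	position_hg38	cds_mutation	sift	polyphen	mutation_taster	in_cgc	reported	freq_normal	freq_tumor	read_depths
T4	PIK3CA	chr3:179218294	c.G1624A	0.016(D)	0.912(D)	1(D)	Yes	Yes	0.73%	35.00%	2%,1+,0-
T5	PIK3CA	chr3:179198937	c.C112T	0.072(T)	0.996(D)	1(D)	Yes	Yes	5.26%	37.86%	38%,28+,12-
T6	PIK3CA	chr3:179221146	c.G2176A	0.808(T)	0.396(B)	1(D)	Yes	Yes	0.00%	9.71%	10%,5+,5-
T7	PIK3CA	chr3:179218303	c.G1633C	0.002(D)	0.734(P)	1(D)	Yes	Yes	0.58%	11.20%	11%,11+,7-
T9	PIK3CA	chr3:179234297	c.A3140T	1(T)	0.07(B)	1(D)	Yes	Yes	0.00%	30.39%	27%,14+,2-
T10	PIK3CA	chr3:179199088	c.G263A	0.054(T)	0.971(D)	1(D)	Yes	Yes	9.63%	80.42%	80%,40+,75-
T2	ADGRB1	chr8:142542406	c.4172_4175del	.	.	.	NO	NO	0.00%	10.39%	–
T6	ADGRB1	chr8:142542106	c.C3872T	0.005(D)	0.966(D)	0.976(D)	NO	NO	0.00%	17.50%	18%,9+,5-
T5	ARHGAP5	chr14:32092620	c.G1951A	0.603(T)	0.008(B)	1(D)	Yes	Yes	3.31%	41.32%	41%,8+,12-
T6	ARHGAP5	chr14:32091046	c.C377G	.	.	1(A)	Yes	Yes	0.00%	11.43%	11%,2+,6-
T10	ARHGAP5	chr14:32091085	c.G416A	0.001(D)	0.997(D)	1(D)	Yes	Yes	2.00%	44.23%	45%,25+,27-
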