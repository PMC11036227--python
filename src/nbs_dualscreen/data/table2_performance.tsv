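center	n_screened	msms_positive	msms_recalled	msms_confirmed	msms_false_negative	msms_diseases	ngs_positive	ngs_recalled	ngs_confirmed	ngs_false_negative	ngs_diseases
SH	4888	47	41	1	0	MMA	1	1	1	0	MMA
GZ	4813	50	47	4	1	MMA,PCD (2),MADD	5	5	4	1	MMA, NICCD, PCD (2)
JN	4797	149	138	6	0	MMA (2),IBD, CPTII, PCD, MCAD	6	6	4	2	MMA (2), PCD, MCAD
SJZ	4899	67	65	2	0	PKU,MSUD	1	1	1	1	PKU
CQ	2988	30	22	2	0	PKU, PCD	3	3	1	1	PKU
YN	3006	43	40	2	1	SCADD,IBD	3	3	3	0	MMA,SCADD, IBD
NMG	3233	113	36	2	0	PKU, MMA	3	3	2	0	PKU, MMA
HN	977	8	8	2	0	PCD,SCADD	2	2	1	1	PCD
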