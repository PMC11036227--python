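disease	gene	n_cases	incidence_reciprocal	carrier_reciprocal	in_panel
cblC-MMA	MMACHC	5	5920	52	true
PCD	SLC22A5	5	5920	63	true
PKU	PAH	3	9867	42	true
SCADD	ACADS	2	14801	127	true
IBD	ACAD8	2	14801	211	true
NICCD	SLC25A13	1	29601	55	true
MCAD	ACADM	1	29601	251	true
CPTII	CPT2	1	29601	580	true
cblA-MMA	MMAA	1	29601	1139	true
MSUD	DBT	1	29601	1480	true
MADD	ETFA	1	29601		false
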