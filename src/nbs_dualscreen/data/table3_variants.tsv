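subject_id	gene	exon	variant_id	protein	acmg_class	zygosity
P1	MMAA	EX2	c.365T>C	p.Leu122Pro	LP	hom
P2	MMACHC	EX1	c.80A>G	p.Gln27Arg	LP	het
P2	MMACHC	EX4E	c.482G>A	p.Arg161Gln	LP	het
P3	MMACHC	EX1	c.80A>G	p.Gln27Arg	LP	het
P3	MMACHC	EX4E	c.609G>A	p.Trp203*	LP	het
P4	MMACHC	EX1	c.80A>G	p.Gln27Arg	LP	het
P4	MMACHC	EX4E	c.609G>A	p.Trp203*	LP	het
P5	MMACHC	EX4E	c.482G>A	p.Arg161Gln	LP	het
P5	MMACHC	EX4E	c.565C>T	p.Arg189Cys	LP	het
P6	MMACHC	EX4E	c.658_660delAAG	p.Lys220del	P	hom
P7	PAH	EX3	c.331C>T	p.Arg111*	P	het
P7	PAH	IVS12	c.1315+6T>A		LP	het
P8	PAH	EX5	c.482T>C	p.Phe161Ser	LP	het
P8	PAH	EX11	c.1197A>T	p.V399V	P	het
P9	PAH	EX6	c.688G>A	p.Val230Ile	LP	het
P9	PAH	EX12	c.1238G>C	p.Arg413Pro	P	het
P10	SLC22A5	EX1	c.51C>G	p.Phe17Leu	LP	hom
P11	SLC22A5	EX2	c.428C>T	p.Pro143Leu	P	het
P11	SLC22A5	EX8	c.1400C>G	p.Ser467Cys	P	het
P12	SLC22A5	EX4	c.760C>T	p.Arg254*	P	het
P12	SLC22A5	EX8	c.1400C>G	p.Ser467Cys	P	het
P13	SLC22A5	EX8	c.1400C>G	p.Ser467Cys	P	hom
P14	ACADS	EX9	c.1031A>G	p.Glu344Gly	P	hom
P15	ACAD8	EX3	c.289G>A	p.Gly97Arg	LP	het
P15	ACAD8	EX4	c.413delA	p.Asn138Metfs*36	P	het
P16	ACADM	IVS10	c.946-1G>C		LP	het
P16	ACADM	EX11	c.1085G>A	p.Gly362Glu	LP	het
P17	SLC25A13	EX16	c.1638_1660dup	p.Ala554Glyfs*17	P	het
P17	SLC25A13	EX9	c.852_855delTATG	p.Met285Profs*2	P	het
P18	DBT	EX2	c.75_76delAT	p.Cys26Trpfs*2	P	het
P18	DBT	EX11E	c.1359_1360delAG	p.Arg453Serfs*3	VUS	het
P19	ACAD8	EX4	c.473A>G	p.Tyr158Cys	VUS	het
P19	ACAD8	EX10	c.1165C>T	p.Arg389Trp	VUS	het
P20	ACADS	EX3	c.322G>A	p.Gly108Ser	LP	het
P20	ACADS	EX6	c.779G>T	p.Gly260Val	VUS	het
P21	SLC22A5	EX8	c.1400C>G	p.Ser467Cys	P	het
P21	SLC22A5	EX3	c.621G>T	p.Gln207His	VUS	het
P22	CPT2	EX1	c.125C>T	p.Thr42Ile	VUS	het
P22	CPT2	EX4	c.1613delA	p.Tyr538Serfs*5	VUS	het
P23	ETFA	EX5	c.369G>A	p.R122K	P	het
P23	ETFA	EX8	c.659delC	p.S220Lfs*6	P	het
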