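subject_id	genetic_call	msms_call	disorder	inheritance	sex
P1	positive	positive	cblA-MMA	AR	F
P2	positive	positive	cblC-MMA	AR	F
P3	positive	positive	cblC-MMA	AR	F
P4	positive	positive	cblC-MMA	AR	F
P5	positive	negative	cblC-MMA	AR	F
P6	positive	positive	cblC-MMA	AR	F
P7	positive	positive	PKU	AR	F
P8	positive	positive	PKU	AR	F
P9	positive	positive	PKU	AR	F
P10	positive	positive	PCD	AR	F
P11	positive	positive	PCD	AR	F
P12	positive	positive	PCD	AR	F
P13	positive	positive	PCD	AR	F
P14	positive	positive	SCADD	AR	F
P15	positive	positive	IBD	AR	F
P16	positive	positive	MCAD	AR	F
P17	positive	negative	NICCD	AR	F
P18	negative	positive	MSUD	AR	F
P19	negative	positive	IBD	AR	F
P20	negative	positive	SCADD	AR	F
P21	negative	positive	PCD	AR	F
P22	negative	positive	CPTII	AR	F
P23	negative	positive	MADD	AR	F
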