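subject_id	stage	marker	value	cutoff	unit
P1	primary	C3	15.19	5	umol/L
P1	recall	C3	9.01	5.5	umol/L
P2	primary	C3	4.4	4.5	umol/L
P2	primary	C3/C2	0.356	0.2	ratio
P2	recall	C3	4.37	4.5	umol/L
P2	recall	C3/C2	0.344	0.2	ratio
P3	primary	C3	3.53	5	umol/L
P3	primary	Met	8.36	9	umol/L
P3	primary	C3/C2	0.18	0.2	ratio
P3	recall	C3	0.92	5	umol/L
P3	recall	Met	7.17	9	umol/L
P3	recall	C3/C2	0.25	0.2	ratio
P4	primary	C3	2.23	4.5	umol/L
P4	primary	C3/C2	0.235	0.2	ratio
P4	recall	C3	3.64	4.5	umol/L
P4	recall	C3/C2	0.44	0.2	ratio
P5	primary	C3	1.99	3.59	umol/L
P5	primary	C3/C2	0.14	0.2	ratio
P5	recall	C3	2.16	4.5	umol/L
P5	recall	C3/C2	0.11	0.22	ratio
P6	primary	C3	9.74	4.8	umol/L
P6	primary	C3/C2	0.57	0.23	ratio
P6	recall	C3	7.83	4.8	umol/L
P6	recall	C3/C2	0.96	0.23	ratio
P7	primary	Phe	276	116	umol/L
P7	primary	Phe/Tyr	3.02	1.5	ratio
P7	recall	Phe	393	116	umol/L
P7	recall	Phe/Tyr	4.57	1.5	ratio
P8	primary	Phe	606	120	umol/L
P8	primary	Phe/Tyr	14.11	1.5	ratio
P8	recall	Phe	10.89		mg/dL
P9	primary	Phe	2.45	2.1	mg/dL
P9	recall	Phe	166	120	umol/L
P9	recall	Phe/Tyr	1.88	1.2	ratio
P10	primary	C0	6.78	10	umol/L
P10	recall	C0	10.09	10	umol/L
P11	primary	C0	7.46	10	umol/L
P11	recall	C0	4.64	10	umol/L
P12	primary	C0	8.82	10	umol/L
P12	recall	C0	4.81	10	umol/L
P13	primary	C0	5.16	9	umol/L
P13	recall	C0	7.76	9	umol/L
P14	primary	C4	2.8	0.46	umol/L
P14	primary	C4/C3	3.79	0.4	ratio
P14	recall	C4	1.98	0.46	umol/L
P14	recall	C4/C3	6.04	0.4	ratio
P15	primary	C4	2.08	0.46	umol/L
P15	primary	C4/C3	4.1	0.4	ratio
P15	recall	C4	1.99	0.46	umol/L
P15	recall	C4/C3	2.02	0.4	ratio
P16	primary	C8	3.64	0.13	umol/L
P16	primary	C8/C10	15.8	1.4	ratio
P16	recall	C8	2.16	0.13	umol/L
P16	recall	C8/C10	12	1.4	ratio
P17	primary	Cit	20.13	30	umol/L
P17	recall	Cit	449.85	35	umol/L
P18	primary	Leu	1088	270	umol/L
P18	primary	Val	602	269	umol/L
P18	recall	Leu	4182.3	270	umol/L
P18	recall	Val	998.6	269	umol/L
P19	primary	C4	1.19	0.5	umol/L
P19	recall	C4	1.23	0.5	umol/L
P20	primary	C4	0.9	0.45	umol/L
P20	recall	C4	2.11	0.45	umol/L
P21	primary	C0	6.65	9	umol/L
P21	recall	C0	8.96	9	umol/L
P22	primary	C12	1.18	0.3	umol/L
P22	primary	C14	2.52	0.4	umol/L
P22	primary	C16	25.1	4.27	umol/L
P22	primary	C18	5.82	1.8	umol/L
P22	primary	C18:1	8.94	3	umol/L
P22	recall	C12	0.9	0.33	umol/L
P22	recall	C14	0.57	0.4	umol/L
P22	recall	C18:1	4.24	3	umol/L
P23	primary	C4	2.19	0.8	umol/L
P23	primary	C5	3.11	0.35	umol/L
P23	primary	C6	1.14	0.12	umol/L
P23	primary	C8	1.76	0.16	umol/L
P23	recall	C4	5.83	0.8	umol/L
P23	recall	C5	6.2	0.35	umol/L
P23	recall	C6	3.15	0.12	umol/L
P23	recall	C8	5.2	0.16	umol/L
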