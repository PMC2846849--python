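row	position	base_change	gene	aa_position	codon_change	aa_change	protein_change	syn_nonsyn	carrier_count	accession
1	2707	G>A	*16s RNA*	-	-	-	-	-	1	-
2	2790	Ins T	*16s RNA*	-	-	-	-	-	2	GU186097
3	3311	C>T	*ND1*	2	CCC>CTC	Pro>Leu	p.P2L	non-syn	1	GU186068
4	3316	G>A	*ND1*	4	GCC>ACC	Ala>Thr	p.A4T	non-syn	1	-
5	3335	T>C	*ND1*	10	ATT>ACT	IsoLeu>Thr	p.I10T	non-syn	1	-
6	3398	T>C	*ND1*	31	ATA>ACA	Met>Thr	p.M31T	non-syn	2	GU186069
7	3480	A>G	*ND1*	58	AAA>AAG	Lys>Lys	p.K58K	syn	2	-
8	3645	T>C	*ND1*	113	GTT>GTC	Val>Val	p.V113V	syn	1	-
9	3741	C>T	*ND1*	145	ACC>ACT	Thr>Thr	p.T145T	syn	1	-
10	3826	T>C	*ND1*	174	TTA>CTA	Leu>Leu	p.L174L	syn	1	-
11	3921	C>T	*ND1*	205	TCC>TCT	Ser>Ser	p.S205S	syn	2	-
12	4216	T>C	*ND1*	304	TAT>CAT	Tyr>His	p.Y304H	non-syn	1	-
13	4225	A>G	*ND1*	307	ATA>GTA	Met>Val	p.M307V	non-syn	1	-
14	4502	T>C	*ND2*	11	TCT>TCC	Ser>Ser	p.S11S	syn	1	GU186070
15	4561	T>C	*ND2*	31	GTA>GCA	Val>Ala	p.V31A	non-syn	1	-
16	4580	G>A	*ND2*	37	ATG>ATA	Met>Iso	p.M37I	non-syn	1	-
17	4615	A>G	*ND2*	49	AAC>AGC	Asn>Ser	p.N49S	non-syn	1	GU186071
18	4638	A>G	*ND2*	57	ATC>GTC	Ile>Val	p.I57V	non-syn	3	GU186072
19	4703	T>C	*ND2*	78	AAT>AAC	Asn>Asn	p.N78N	syn	1	-
20	4916	A>G	*ND2*	149	CTA>CTG	Leu>Leu	p.L149L	syn	1	-
21	4917	A>G	*ND2*	150	AAC>GAC	Asn>Asp	p.N150D	non-syn	1	-
22	4944	A>G	*ND2*	159	ATC>GTC	Ile>Val	p.I159V	non-syn	1	-
23	5033	A>G	*ND2*	188	GGA>GGG	Gly>Gly	p.G188G	syn	1	-
24	5097	A>G	*ND2*	210	ATC>GTC	Ile>Val	p.I210V	non-syn	1	GU186073
25	5186	A>T	*ND2*	239	TGA>TGT	Trp>Cys	p.W239C	non-syn	4	-
26	5252	G>A	*ND2*	261	TTG>TTA	Leu>Leu	p.L261L	syn	1	-
27	5360	C>T	*ND2*	297	ATC>ATT	Ile>Ile	p.I297I	syn	1	-
28	6011	T>C	*CO1*	36	CTT>CTC	Leu>Leu	p.L36L	syn	1	-
29	6023	G>A	*CO1*	4O	GAG>GAA	Glu>Glu	p.E40E	syn	1	-
30	6217	T>C	*CO1*	105	TTA>CTA	Leu>Leu	p.L105L	syn	1	GU186074
31	6290	C>T	*CO1*	129	TAC>TAT)	Tyr>Tyr	p.Y129Y	syn	3	-
32	6366	G>A	*CO1*	155	GTC>ATC	Val>Ile	p.V155 I	non-syn	3	-
33	6584	C>T	*CO1*	227	GAC>GAT	Asp>Asp	p.D227D	syn	1	GU186075
34	7280	C>T	*CO1*	459	TTC>TTT	Phe>Phe	p.F459F	syn	2	GU186076
35	7598	G>A	*CO2*	5	GCG>ACG	Ala>Thr	p.A5T	non-syn	1	-
36	7746	A>G	*CO2*	54	AAC>AGC	Asn>Ser	p.N54S	non-syn	1	GU186077
37	7843	A>G	*CO2*	86	ATA>ATG	Met>Met	p.M86M	syn	3	-
38	7868	C>T	*CO2*	95	CTT>TTT	Leu>Phe	p.L95F	non-syn	2	-
39	7961	T>C	*CO2*	126	TTA>CTA	Leu>Leu	p.L126L	syn	1	-
40	7962	T>C	*CO2*	126	TTA>TCA	Leu>Ser	p.L126S	non-syn	1	GU186078
41	8023	T>C	*CO2*	146	ATT>ATC	Ile>Ile	p.I 146 I	syn	1	-
42	8116	A>G	*CO2*	177	GGA>GGG	Gly>Gly	p.G177G	syn	1	GU186079
43	8136	T>C	*CO2*	184	TTC>TTT	Phe>Phe	p.F184F	syn	32	-
44	8252	G>A	*CO2*	222	GGG>GGA	Gly>Gly	p.G222G	syn	2	-
45	8346	C>T	*t RNA Lys*	-	-	-	-	-	1	GU186096
46	8396	A>G	*ATPase8*	11	ACC>GCC	Thr>Ala	p.T11A	non-syn	1	GU186091
47	8485	G>A	*ATPase8*	40	AAG>AAA	Lys>Lys	p.K40K	syn	1	GU186092
48	8502	A>G	ATPase8	46	AAT>AGT	Asn>Ser	p.N46S	non-syn	1	GU186091
49	8584	G>A	*ATPase6*	20	GCA>ACA	Ala>Thr	p.A20T	non-syn	2	-
50	8658	C>T	*ATPase6*	44	ACC>ACT	Thr>Thr	p.T44T	syn	1	GU186080
51	8684	C>T	*ATPase6*	53	ACC>ATC	Thr>Ile	p.T53I	non-syn	1	-
52	8697	G>A	*ATPase6*	57	ATG>ATA	Met>Met	p.M57M	syn	1	-
53	8701	G>A	*ATPase6*	59	GCC>ACC	Ala>Thr	p.A59T	non-syn	15	-
54	8843	T>A	*ATPase6*	106	ATC>ACC	Ile>Ile	p.I106 I	syn	2	-
55	8865	G>A	*ATPase6*	113	GTG>GTA	Val>Val	p.V113V	syn	2	-
56	8875	T>C	*ATPase6*	117	TTT>CTT	Phe>Thr	p.F117T	non-syn	1	GU186081
57	8886	G>A	*ATPase6*	120	AAG>AAA	Lys>Lys	p.K120K	syn	35	GU186095
58	8887	A>G	*ATPase6*	121	ATT>GTT	Ile>Val	p.I121V	non-syn	1	-
59	8925	A>G	*ATPase6*	133	ACA>ACG	Thr>Thr	p.T133T	syn	1	-
60	8928	T>C	*ATPase6*	138	ATC>ACC	Ile>Thr	p.I138T	non-syn	1	-
61	8943	C>T	*ATPase6*	139	CCC>CCT	Pro>Pro	p.P139P	syn	1	-
62	9064	G>A	*ATPase6*	180	GCA>ACA	Ala>Thr	p.A180T	non-syn	2	-
63	9072	A>G	*ATPase6*	183	TCA>TCG	SerSer	p.S183S	syn	1	-
64	9094	C>T	*ATPase6*	190	CTT>TTT	Leu>Phe	p.L190F	non-syn	1	-
65	9110	T>C	*ATPase6*	195	ATT>ACT	Ile>Thr	p.I195T	non-syn	1	-
66	9287	G>A	*CO3*	27	ATG>ATA	Met>Met	p.M27M	syn	1	GU186089
67	9377	G>A	*CO3*	57	TGA>TGG	Trp>Trp	p.W57W	syn	19	-
68	9540	C>T	*CO3*	112	CTA>TTA	Leu>Leu	p.L112L	syn	9	-
69	9614	A>G	*CO3*	136	GTA>GTG	Val>Val	p.V136V	syn	1	-
70	9698	T>C	*CO3*	164	CTT>CTC	Leu>Leu	p.L164L	syn	1	-
71	9716	T>C	*CO3*	170	GGT>GGC	Gly>Gly	p.G170G	syn	1	-
72	9767	C>T	*CO3*	183	ACC>ACT	Thr>Thr	p.T187T	syn	1	-
73	9768	T>C	*CO3*	184	TCT>TCC	Ser>Ser	p.S184S	syn	1	-
74	9967	G>A	*CO3*	254	GTC>ATC	Val>Ile	p.V254I	non-syn	1	GU186090
75	10142	C>T	*ND3*	28	AAC>AAT	Asn>Asn	p.N28N	syn	1	-
76	10181	C>T	*ND3*	41	TTC>TTT	Phe>Phe	p.F41F	syn	1	-
77	10365	G>C	*ND3*	103	GCC>ACC	Ala>Thr	p.A103T	non-syn	1	-
78	10398	G>A	*ND3*	114	GCC>ACC	Ala>Thr	p.A114T	non-syn	16	-
79	10400	C>T	*ND3*	114	GCC>GCT	Ala>Ala	p.A114A	syn	12	-
80	10410	T>A	*tRNA Arg*	-	-	-	-	-	1	-
81	10463	T>C	*tRNA Arg*	-	-	-	-	-	1	-
82	10490	T>C	*ND4L*	7	AAT>AAC	Asn>Asn	p.N7N	syn	1	GU186094
83	10550	A>G	*ND4L*	27	ATA>ATG	Met>Met	p.M27M	syn	1	-
84	11467	A>G	*ND4*	236	TTA>TTG	Leu>Leu	p.L236L	syn	2	-
85	11719	A>G	*ND4*	320	GGA>GGG	Gly>Gly	p.G320G	syn	2	-
86	12007	G>A	*ND4*	416	TGG>TGA	Trp>Trp	p.W416W	syn	5	-
87	12031	C>T	*ND4*	424	AAC>AAT	Asn>Asn	p.N424N	syn	1	GU186088
88	12097	C>T	*ND4*	446	CTC>CTT	Leu>Leu	p.L446L	syn	2	-
89	12106	C>T	*ND4*	449	CTC>CTT	Leu>Leu	p.L449L	syn	1	-
90	12130	T>C	*ND4*	457	TTT>TTC	Phe>Phe	p.F457F	syn	1	GU186087
91	12308	A>G	*tRNA Leu*	-	-	-	-	-	3	-
92	12372	G>A	*ND5*	12	CTG>CTA	Leu>Leu	p.L12L	syn	4	-
93	12477	T>C	*ND5*	47	AGT>AGC	Ser>Ser	p.S47S	syn	1	-
94	12498	C>T	*ND5*	54	TTC>TTT	Phe>Phe	p.F54F	syn	2	-
95	12561	G>A	*ND5*	75	CAG>CAA	Gln>Gln	p.Q75Q	syn	1	-
96	12681	T>C	*ND5*	115	AAT>AAC	Asn>Asn	p.N115N	syn	1	-
97	12705	T>C	*ND5*	123	ATT>ATC	Ile>Ile	p.I123 I	syn	10	-
98	12793	T>C	*ND5*	153	TTG>CTG	Leu>Leu	p.L153L	syn	1	GU186084
99	12810	A>G	*ND5*	158	TGA>TGG	Trp>Trp	p.W158W	syn	1	-
100	12849	A>T	*ND5*	171	GCA>GCT	Ala>Ala	p.A171A	syn	8	GU186085
101	12879	T>C	*ND5*	181	GGT>GGC	Gly>Gly	p.G181G	syn	1	-
102	12906	C>T	*ND5*	190	ATC>ATT	Ile>Ile	p.I190I	syn	1	GU186082
103	13020	T>C	*ND5*	228	GGT>GGC	Gly>Gly	p.G228G	syn	1	-
104	13135	G>A	*ND5*	267	GCA>ACA	Ala>Thr	p.A267T	non-syn	1	-
105	13138	G>A	*ND5*	268	GAA>AAA	Glu>Lys	p.E268K	non-syn	20	GU186083
106	13188	C>T	*ND5*	284	ACC>ACT	Thr>Thr	p.T284T	syn	1	-
107	13194	G>A	*ND5*	286	CTG>CTA	Leu>Leu	p.L286L	syn	1	-
108.	13215	T>C	*ND5*	293	CTT>CTC	Leu>Leu	p.L293L	syn	1	-
109	13368	G>A	*ND5*	344	GGG>GGA	Gly>Gly	p.G344G	syn	1	-
110	13500	T>C	*ND5*	388	GGT>GGC	Gly>Gly	p.G388G	syn	1	-
111	13539	A>G	*ND5*	401	ATA>ATG	Met>Met	p.M401M	syn	2	-
112	13542	A>G	*ND5*	402	TCA>TCG	Ser>Ser	p.S402S	syn	1	-
113	13651	A>G	*ND5*	439	ACC>GCC	Thr>Ala	p.T439A	non-syn	1	-
114	13656	T>C	*ND5*	440	CTT>CTC	Leu>Leu	p.L440L	syn	4	-
115	13708	G>A	*ND5*	458	GCA>ACA	Ala>Thr	p.A458T	non-syn	1	-
116	13768	T>C	*ND5*	478	TTC>CTC	Phe>Leu	p.F478L	non-syn	1	GU186086
117	14000	T>A	*ND5*	555	CCT>CCA	Leu>Pro	p.L555P	non-syn	2	-
118	14022	A>G	*ND5*	562	TTA>TTG	Leu>Leu	p.L562L	syn	1	-
119	14935	T>C	*CYB*	63	TTT>TTC	Phe>Phe	p.F63F	syn	1	-
120	15038	A>G	*CYB*	98	ATC>GTC	Ile>Val	p.I98V	non-syn	1	-
121	15043	G>A	*CYB*	99	GGG>GGA	Gly>Gly	p.G99G	syn	12	-
122	15061	A>G	*CYB*	105	GGA>GGG	Gly>Gly	p.G105G	syn	1	-
123	15097	T>C	*CYB*	117	ATT>ATC	Ile>Ile	p.I117I	syn	1	-
124	15148	G>A	*CYB*	134	CCG>CCA	Pro>Pro	p.P134P	syn	3	-
125	15301	G>A	*CYB*	185	TTG>TTA	Leu>Leu	p.L185L	syn	16	-
126	15317	G>A	*CYB*	191	GCC>ACC	Ala>Thr	p.A191T	non-syn	1	-
127	15452	C>A	*CYB*	236	CTT>ATT	Leu>Ile	p.L236 I	non-syn	2	-
128	15607	A>G	*CYB*	287	AAA>AAG	Lys>Lys	p.K287K	syn	1	-
129	15670	T>C	*CYB*	308	CAT>CAC	His>His	p.H308H	syn	1	-
130	15683	A>G	*CYB*	312	CAA>CAG	Gln>Gln	p.Q312Q	syn	2	GU186093
131	At 15928	G>A	*t RNA Thr*	-	-	-	-	-	1	-
132	At 15930	G>A	*t RNA Thr*	-	-	-	-	-	1	-
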