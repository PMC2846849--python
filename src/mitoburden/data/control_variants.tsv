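row	position	base_change	gene	aa_position	codon_change	aa_change	protein_change	syn_nonsyn	accession
1	3591	G>A	*ND1*	95	CTG>CTA	Thr>Thr	p.T95T	syn	-
2	3915	G>A	*ND1*	203	GGG>GGA	Gly>Gly	p.G203G	syn	-
3	3918	G>A	*ND1*	204	GAG>GAA	Glu>Glu	p.E204E	syn	-
4	3933	A>G	*ND1*	209	TCA>TCG	Ser>Ser	p.S209S	syn	GU397544
5	3970	C>T	*ND1*	222	CTA>TTA	Leu>Leu	p.L222L	syn	-
6	3996	C>T	*ND1*	230	AAC>AAT	Asn>Asn	p.N230N	syn	-
7	4029	C>A	*ND1*	241	ATC>ATA	Ile>Ile	p.I241I	syn	GU397545
8	4093	A>G	*ND1*	263	ACC>GCC	Thr>Ala	p.T263A	non-syn	-
9	4793	A>G	*ND2*	108	ATA>ATG	Met>Met	p.M108M	syn	-
10	4852	T>A	*ND2*	128	CTG>CAG	Leu>Gln	p.L128Q	non-syn	GU397533
11	5186	A>T	*ND2*	239	TGA>TGT	Trp>Cys	p.W239C	non-syn	-
12	5348	C>T	*ND2*	293	TAC>TAT	Tyr>Tyr	p.Y293Y	syn	-
13	5351	A>G	*ND2*	294	CTA>CTG	Leu>Leu	p.L294L	syn	-
14	6305	G>A	*CO1*	134	GGG>GGA	Gly>Gly	p.G134G	syn	-
15	6719	T>C	*CO1*	272	GGT>GGC	Gly>Gly	p.G272G	syn	-
16	6962	G>A	*CO1*	353	CTG>CTA	Thr>Thr	p.T353T	syn	-
17	7316	G>A	*CO1*	471	ATG>ATA	Met>Met	p.M471M	syn	–
18	7738	T>C	*CO2*	51	ACT>ACC	Thr>Thr	p.T51T	syn	-
19	7762	G>A	*CO2*	59	CAG>CAA	Gln>Gln	p.Q59Q	syn	-
20	8143	T>C	*CO2*	186	GCT>GCC	Ala>Ala	p.A186A	syn	GU397549
21	8251	G>A	*CO2*	222	GGG>GGA	Gly>Gly	p.G222G	syn	-
22	8503	T>G	*ATP8*	46	AAT>AAG	Asp>Lys	p.N46K	non-syn	GU397551
23	8584	G>A	*ATP6*	20	GCA>ACA	Ala>Thr	p.A20T	non-syn	-
24	8594	T>C	*ATP6*	23	ATC>ACC	Ile>Thr	p.I23T	non-syn	-
25	8650	C>T	*ATP6*	42	CTA>TTA	Leu>Leu	p.L42L	syn	-
26	8718	A>G	*ATP6*	64	AAA>AAG	Lys>Lys	p.K64K	syn	-
27	8812	A>G	*ATP6*	96	ACC>GCC	Thr>Ala	p.T96A	non-syn	-
28	8886	G>A	*ATP6*	120	AAG>AAA	Lys>Lys	p.K120K	syn	GU397552
29	8925	A>G	*ATP6*	133	ACA>ACG	Thr>Thr	p.T133T	syn	-
30	10310	G>A	*ND3*	84	CTG>CTA	Thr>Thr	p.T84T	syn	-
31	10609	T>C	*ND4L*	47	ATA>ACA	Met>Thr	p.M47T	non-syn	-
32	11467	A>G	*ND4*	236	TTA>TTG	Leu>Leu	p.L236L	syn	-
33	11914	G>A	*ND4*	385	ACG>ACA	Thr>Thr	p.T385T	syn	-
34	12007	G>A	*ND4*	416	TGG>TGA	Trp>Trp	p.W416W	syn	-
35	12073	C>T	*ND4*	438	TTC>TTT	Phe>Phe	p.F438F	syn	GU397542
36	12107	C>T	*ND4*	449	CTC>CTT	Thr>Thr	p.T449T	syn	GU397543
37	12133	C>T	*ND4*	458	TCC>TCT	Ser>Ser	p.S458S	syn	-
38	12372	G>A	*ND5*	12	CTG>CTA	Tyr>Tyr	p.T12T	syn	-
39	12373	A>G	*ND5*	13	ACT>GCT	Thr>Ala	p.T13A	non-syn	-
40	12406	G>A	*ND5*	24	GTT>ATT	Val>Ile	p.V24I	non-syn	-
41	12486	C>T	*ND5*	50	CCC>CCT	Pro>Pro	p.P50P	syn	GU397534
42	12498	C>T	*ND5*	54	TTC>TTT	Phe>Phe	p.F54F	syn	GU397538
43	12561	G>A	*ND5*	75	CAG>CAA	Gln>Gln	p.Q75Q	syn	-
44	13204	G>A	*ND5*	290	GTC>ATC	Val>Ile	p.V290I	non-syn	GU397535
45	13299	A>G	*ND5*	321	CAA>CAG	Gln>Gln	p.Q321Q	syn	-
46	13676	A>G	*ND5*	447	AAC>AGC	Asn>Ser	p.N447S	non-syn	GU397540
47	13731	A>G	*ND5*	465	GGA>GGG	Gly>Gly	p.G465G	syn	-
48	13860	C>T	*ND5*	490	GCC>GCT	Ala>Ala	p.A490A	syn	GU397541
49	14058	C>T	*ND5*	574	TCC>TCT	Ser>Ser	p.S574S	syn	-
50	14783	T>C	*CYB*	13	TTA>CTA	Leu>Leu	p.L13L	syn	-
51	14872	C>T	*CYB*	42	ATC>ATT	Ile>Ile	p.I42I	syn	-
52	15119	G>A	*CYB*	125	GCA>ACA	Ala>Thr	p.A125T	non-syn	-
53	15172	G>A	*CYB*	142	GGG>GGA	Gly>Gly	p.G142G	syn	-
54	15217	G>A	*CYB*	157	GGG>GGA	Gly>Gly	p.G157G	syn	-
55	15385	C>T	*CYB*	213	TCC>TCT	Ser>Ser	p.S213S	syn	-
56	15431	G>A	*CYB*	229	GCC>ACC	Ala>Thr	p.A229T	non-syn	-
57	15484	A>G	*CYB*	246	TCA>TCG	Ser>Ser	p.S246S	syn	GU397547
58	15670	T>C	*CYB*	308	CAT>CAC	His>His	p.H308H	syn	-
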