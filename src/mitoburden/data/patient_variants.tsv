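patient	ND1	ND2	CO1	CO2	ATPase8	ATPase6	CO3	ND3	ND4L	ND4	ND5	CYB	other_changes	cup_disc_ratio	corneal_diameter_mm	iop_mmhg
1	–	–	p.Y129Y; p.F459F	p.M86M; p.L95F	–	p.A20T; p.A59T	p.W57W; p.L112L	p.A114T	-	–	p.I123I; p.E268K; p.M401M; p.L555P	p.P134P; p.L185L	Ins. of T at 2790_91 (16sRNA)	Total cupping	15x15/15x15.5	40/30
2	–	–	p.Y129Y; p.F459F	p.M86M; p.L95F	–	p.A20T; p.A59T	p.W57W; p.L112L	p.A114T	-	–	p.I123I; p.E268K; p.M401M; p.L555P	p.P134P; p.L185L	Ins. of T at 2790_91 (16sRNA)	0.8:1/0.8:1	13x13/13x13	36/40
3	p.M31T		p.V155 I		–	p.V113V	p.W57W	p.A114A	-	p.W416W	p.E268K	p.G99G	-	Hazy MEDIA	15x14/15x15	26/38
4	–	–	p.D227D	G222G	–	I195T	W57W	A114A	-	p.W416W	p. E268K	p.A191T; p.Q312Q	-	0.4:1/0.4:1	12x11/12x12	22/24
5	–	–	–	p.N54S	–	p.A59T	p.W57W; p.L112L	p.A114T	-		p.I190I; p.E268K	p.G99G; p.L185L	-	0.7:1/0.7:1	14.5x15/15x15	28/28
6	p.Y304H; p.M307V	p.N150T	–	–		p.M57M	p.W57W; p.L112L	p.A114T	-	–	p. I123I; p.E268K; p.G344G	p.L236I; p.K287Q	-	0.5:1/0.5:1	12x13/12x13	22/23
7	–	–	–	p.I146I; p.F184F	–	p.A59T; p.P139P	p.M27M; p.W57W; p.L112L; p.T187T	p.A114T	-	p.L236L	p.I123I; p.E268K	p.F63F; p.G99G; p.G105G; p.L185L	A>G at 12308 tRNA Leu	0.4:1/0.4:1	12x13/11x11.5	38/14
8	–	–	–	p.G177G	–	–	p.W57W	p.A114A	-	–	p.Q75Q; p.E268K	p.G99G	G>A at 15928 (t RNA Thr)	Hazy media	NA	23/25
9	p.L174L; p.S205S	–	–	–	–	–	p.W57W	p.A114A	-	–	p.I123I; p.V172I; p.E268K; p.L293L	p.G99G	C>T at 8346 (t RNA Lys)	NA	12x12/12x12	22/22
10	p.V113V; p.T145T	p.S11S; p.I297I		L126S; F184F		p.I106I; p.T53 I	p.W57W; p.L112L	p.N28N; p.A114T	-	p.L236L	p.I123I; p.E268K; p.G388G	–	A>G at 12308 tRNA Leu	NA	NA	23/24
11	–	p.W239C	p.L105T	–	–	p.A59T; p.L190F	p.W57W; p.L112L; p.V136V	p.A114T	-	p.L449L	p.I123I; p.L153L; p.E268K; p.L286L	p.L185L	G>A at 2707 (16sRNA); A>G at 12308 tRNA Leu; G>A at 15930 tRNA Arg	NA	14x14/14x15	26/22
12	p.P2L	p.N49S	–	–	–	A59T; I106I	–	p.A114T	-	p.G320G	p.N115N; p.I123I; p.E268K; p.L440L; p.A458T; p.F478L	p.L185L	-	NA	14x14.5/14x14.4	32/32
13	p.M31T	–	p.V155 I	–	–	p.V113V	p.W57W	p.A114A	-	p.W416W	p.A171A; E268K	p.G99G	-	Hazy media	14x14/14x14	31/30
14	–	–	–	–	–	p.S183S	p.W57W	p.A114A	-	p.W416W	p.A171A; p.E268K; p.T284T	p.G99G	-	Hazy media	NA	25/24
15	–	p.L261L	–	p.L126L	p.T11A; p.N46S	–	p.W57W; p.S184S	p.A114A	-	–	p.A171A; p.E268K	p.G99G; p.H308H	-	0.6:1/0.6:1	14.5x14/13.5x13	32/32
16	–	–	–	–	p.K40K	–	p.W57W	p.A114A	-	p.W416W	p.F54F; p.A171A; p.A267T; p.E268K	p.G99G	-	0.4:1/0.5:1	11x11/12x12.5	18/26
17	p.S205S	–	–	–	–	p.T44T	p.W57W	p.A114A	-	p.F457F	S47S; A171A; G181G; E268K	p.G99G	-	NA	14x14/14x14.5	30/28
18	–	–	–	–	–	p.A59T	p.W57W; p.L112L	p.A114T	-	p.G320G	p.I123I; p.A171A; p.E268K	p.L185L; p.Q312Q	-	NA	14.5x14/14x14	20/20
19	–	–	p.V155 I	p.A5T	–	p.F17T; p.A180T	p.W57W	p.A103T; p.A114A	-	–	p.A171A; p.G228G; p.E268K	p.G99G	-	0.5:1 1	12x12.5/12x12	22/22
20	p.I10T	–	p.Y129Y	p.M86M	–	p.A59T	p.W57W; p.L112L	p.A114T	-	–	p.I123I; p.V172I	p.I98V; p.P134P; p.L185L	-	Hazy media	12x13/13x13	18/37
21	–	p.I59V	–	–	–	p.K120K	–	–	-	p.L446L	–	p.L185L	-	Hazy media	15x16/11.5x12	32/15
22	–	–	–	p.G222G	–	p.K120K		p.A114A	-	-	–		-	0.7:1/0.5:1	15x15/16x16	28/28
23	p.K58K	p.V31A		–	–	p.A59T; p.K120K	p.L164L; p.G170G	p.A114T	p.M27M	-	p.L12L	p.L185L	-	Hazy media	14x15/14x15	34/36
24	–		–	–	–	p.A59T; p.K120K; p.P134P	-		-	-	–	p.L185L; p.L236I	T>A at 10411 (t RNA Arg)	0.7:1/0.7:1	NA	32/10
25	–	p.I57V; p.W239C	–	–	–	p.A59T; p.K120K	-	p.A114T	-	-	p.L12L; p.L440L	–	-	NA	14x15/14x15	22/22
26	–	p.I57V; p.W239C	–	–	–	p.A59T; p.K120K	-	p.A114T	-	-	p.L12L; p.L440L	–	-	Hazy media	13x13.5/15x14.5	22/22
27	–	p.L149L; p.G188G	–	–	–	p.K120K	-	p.A114A	-	-	p.T439A	p.L185L	-	0.8:1/0.8:1	13x13.5/13x13.5	20/20
28	–	p.M37I; p.N78N	–	–	–	p.K120K	-	p.A114A	-	-	–	p.G99G	-	hazy media	14x14/14x14	22/24
29	–	–	p.E40E	–	–	p.A59T; p.K120K	-	p.A114T	p.N7N	-	–	–	-	NA	14x14/11x11	18/22
30	p.A4T	–	–	–	–	p.K120K ; p.I121V	V254I	p.F41F; p.A114T	-	p.N424N	–	p.L185L	-	Hazy media	corneal ulcer/14x14	18/20
31	–	p.I210V	p.L36L	–	–	p.K120K	-	p.A114A	-	-	–	p.I117I	-	Hazy media	12x10/12x12.5	40/26
32	–	p.I57V; p.W239C	–	–	–	p.A59T; p.K120K; p.A180T	-	p.A114T	-	-	p.L12L	p.L185L	-	0.8:1 1	12x12/12x12	22/26
33	–	–	–	–	–	p.K120K	-	–	-	-	–	p.L185L	-	0.8:1/0.9:1	14x14/14x14	26/24
34	–	–	–	-	-	p.K120K; p.T133T	-	p.A114A	-	-	p.S402S	–	-	0.5:1/0.5:1	12x12/12x12.5	20/22
35	p.K58K	–	–	–	–	p.K120K	-	p.A114A	-	p.L446L	–	–	–	0.5:1/0.3:1	13x13/13x13.5	24/16
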