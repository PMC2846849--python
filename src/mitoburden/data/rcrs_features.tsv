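gene	start	end	strand	kind	complex	incomplete_stop
tRNA-Phe	577	647	H	tRNA	RNA	0
12S	648	1601	H	rRNA	RNA	0
tRNA-Val	1602	1670	H	tRNA	RNA	0
16S	1671	3229	H	rRNA	RNA	0
tRNA-Leu1	3230	3304	H	tRNA	RNA	0
ND1	3307	4262	H	CDS	I	1
tRNA-Ile	4263	4331	H	tRNA	RNA	0
tRNA-Gln	4329	4400	L	tRNA	RNA	0
tRNA-Met	4402	4469	H	tRNA	RNA	0
ND2	4470	5511	H	CDS	I	1
tRNA-Trp	5512	5579	H	tRNA	RNA	0
tRNA-Ala	5587	5655	L	tRNA	RNA	0
tRNA-Asn	5657	5729	L	tRNA	RNA	0
tRNA-Cys	5761	5826	L	tRNA	RNA	0
tRNA-Tyr	5826	5891	L	tRNA	RNA	0
CO1	5904	7445	H	CDS	IV	0
tRNA-Ser1	7446	7514	L	tRNA	RNA	0
tRNA-Asp	7518	7585	H	tRNA	RNA	0
CO2	7586	8269	H	CDS	IV	0
tRNA-Lys	8295	8364	H	tRNA	RNA	0
ATPase8	8366	8572	H	CDS	V	0
ATPase6	8527	9207	H	CDS	V	0
CO3	9207	9990	H	CDS	IV	1
tRNA-Gly	9991	10058	H	tRNA	RNA	0
ND3	10059	10404	H	CDS	I	1
tRNA-Arg	10405	10469	H	tRNA	RNA	0
ND4L	10470	10766	H	CDS	I	0
ND4	10760	12137	H	CDS	I	1
tRNA-His	12138	12206	H	tRNA	RNA	0
tRNA-Ser2	12207	12265	H	tRNA	RNA	0
tRNA-Leu2	12266	12336	H	tRNA	RNA	0
ND5	12337	14148	H	CDS	I	0
ND6	14149	14673	L	CDS	I	0
tRNA-Glu	14674	14742	L	tRNA	RNA	0
CYB	14747	15887	H	CDS	III	1
tRNA-Thr	15888	15953	H	tRNA	RNA	0
tRNA-Pro	15956	16023	L	tRNA	RNA	0
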