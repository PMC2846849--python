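gene	cases	controls	p_value	rr_ci
*ND1*	6 (17.14%)	2 (5.0%)	0.136	1.73 (1.07–2.81)
*ND2*	10 (28.57%)	2 (5.0%)	0.005	2.10 (1.41–3.12)
*ND3*	17 (48.60%)	0 (0%)	<0.001	3.22 (2.19–4.72)
*ND4*	0 (0%)	0 (0%)	—-	—–
*ND4L*	0 (0%)	2 (5.0%)	0.495	1.92 (1.54–2.39)
*ND5*	21 (60.00%)	4 (10.0%)	<0.001	3.00 (1.86–4.83)
*CO1*	4 (11.42%)	0 (0%)	0.043	2.29 (1.75–2.98)
*CO2*	5 (14.30%)	0 (0%)	0.019	2.33 (1.78–3.05)
*CO3*	1 (2.90%)	0 (0%)	0.467	2.17 (1.70–2.78)
*CYB*	4 (11.42%)	8 (20.00%)	0.360	0.57 (0.18–1.73)
*ATPase6*	18 (51.42%)	7 (17.50%)	0.002	2.12 (1.34–3.34)
*ATPase8*	1 (2.85%)	1 (2.5)	1.00	1.07 (0.26–4.40)
Others	8 (22.85%)	0 (0%)	0.001	2.48 (1.85–3.32)
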