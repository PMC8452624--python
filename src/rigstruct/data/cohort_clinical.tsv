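id	age	histology	dose_gy	field	latency_y	status	survival_months
1	–	ALL	–	–	–	–	–
2	14.3	G,O	59.4	Focal	9	D	–
2B	–	G,O	–	–	–	–	–
5	3.6	C	54	Focal	12	D	–
6	7.1	M	–	–	6	D	–
7	–	M	–	–	–	–	–
8	–	Ge	–	–	–	–	–
9	–	M	–	–	–	–	–
11	0.16	G,O	–	Focal	13	D	–
12	3.5	ALL	24	CR	13	D	–
12B	–	ALL	–	–	–	–	–
13	0.3	G,O	49.5	Focal	3	D	–
14	1.5	ALL	18	CSI	8	D	–
14B	–	ALL	–	–	–	–	–
15	12.4	Ge	51	Focal	7	D	–
16	5.8	M	X, 55.8	CSI	7	D	–
18	10.2	M	23.4, 55.8	Focal	8	D	–
19	8	M	X, 55.8	Focal	3	D	–
20	15	Ga	–	Focal	4	–	–
21	7	BL	–	CSI	7	D	–
22	–	ALL	–	TBI	–	D	–
23	8	M	24, 54–55.8	CSI	4	D	–
24	10	M	23.4, 54	CSI	13	D	–
25	11	E	54	Focal	12	D	–
26	3	ALL	–	CR	13	D	–
27	4	M	23.4, 54	CSI	7	D	–
28	19	M	36, 54	CSI	7	D	–
29	3	ALL	21	CR	4	D	–
30	2	ALL	18	CR	10	D	–
31	4	M	X, 54–55.8	CSI	7	D	–
32	9	ALL	12	TBI	–	D	–
33	7	M	23.4, 54	CSI	10	D	–
34	6	ALL	–	TBI	8	D	–
42	8.8	E	–	–	23	–	–
43	2.3	ALL	–	–	11	D	–
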