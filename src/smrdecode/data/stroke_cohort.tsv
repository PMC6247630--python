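patient	group	gender	age_years	months_since_stroke	lesion_side	cfma
1	Exp	M	69	72	L	5.5
2	Exp	M	51	139	R	24
3	Exp	F	35	60	R	25.5
4	Exp	M	48	45	R	7.5
5	Exp	M	70	23	L	8
6	Exp	M	57	122	R	17
7	Exp	M	29	25	R	15
8	Exp	M	60	130	L	9.5
9	Exp	F	35	28	R	11
10	Exp	F	53	30	R	5
11	Exp	F	36	16	L	11
12	Exp	F	72	44	L	2
13	Exp	F	55	45	L	16.5
14	Exp	M	65	45	R	3.5
15	Exp	M	47	80	R	12
16	Exp	F	52	156	L	5.5
17	Sham	F	73	23	R	1
18	Sham	M	51	16	L	3.5
19	Sham	M	50	215	L	33.5
20	Sham	F	55	17	R	0.5
21	Sham	M	54	121	R	16
22	Sham	F	66	23	L	16.5
23	Sham	F	54	10	L	8
24	Sham	M	69	89	R	26
25	Sham	M	40	53	R	3.5
26	Sham	M	47	232	R	13.5
27	Sham	M	66	48	R	7.5
28	Sham	M	58	28	R	8.5
29	Sham	M	40	46	L	30.5
30	Sham	F	53	20	L	17.5
31	Sham	M	63	120	L	8.5
32	Sham	M	55	51	L	22.5
33	C-	F	65	67	L	8.5
34	C-	F	65	131	L	7.5
35	C-	M	65	99	L	7
36	C-	F	31	15	L	33.5
37	C-	M	60	14	L	13
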