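accession	gene	reg_p7	reg_p637	svq	h	score	qm	group
P08461	Dlat	-	up	0.32	5	241	28	carbohydrate metabolism
P04764	Eno1	down	-	1.90	5	107	12	carbohydrate metabolism
P07323	Eno2	down	-	2.22	6	272	32	carbohydrate metabolism
P04797	Gapdh	down	-	3.09	6	262	34	carbohydrate metabolism
P04636	Mdh2	-	up	0.49	5	242	24	carbohydrate metabolism
Q5XI78	Ogdh	down	-	1.93	4	158	18	carbohydrate metabolism
P49432	Pdhb	down	-	5.80	6	139	18	carbohydrate metabolism
D3Z955	Pgm2l1	up	-	0.52	6	126	17	carbohydrate metabolism
P50137	Tkt	down	-	2.09	6	339	35	carbohydrate metabolism
Q6Q0N1	Cndp2	-	up	0.48	5	205	29	amino acid metabolism
Q4V7C6	Gmps	up	-	0.52	5	130	17	amino acid metabolism
P14882	Pcca	down	-	2.14	5	262	32	amino acid metabolism
Q5XI22	Acat2	-	up	0.42	4	180	16	fat metabolism
O35263	Pafah1b3	up	-	0.27	6	135	11	fat metabolism
Q568Z9	Phyhip	up	-	0.54	4	160	17	fat metabolism
P15999	Atp5a1	down	up	3.49	5	295	38	energy metabolism
P31399	Atp5h	down	-	2.70	6	148	13	energy metabolism
Q561S0	Ndufa10	down	-	3.09	4	261	21	energy metabolism
Q641Y2	Ndufs2	down	-	2.46	6	247	31	energy metabolism
D3ZG43	Ndufs3	down	-	3.29	6	280	21	energy metabolism
P19234	Ndufv2	down	-	2.48	5	138	13	energy metabolism
P19234	Ndufv2	down	-	2.48	5	138	13	energy metabolism
P60901	Psma6	up	-	0.48	6	173	16	degradation
P40112	Psmb3	up	-	0.27	5	124	12	degradation
D4A640	Psmb4	up	-	0.56	6	102	7	degradation
Q9JHW0	Psmb7	up	-	0.44	6	120	10	degradation
Q4V8E2	Psmd14	up	-	0.56	4	64	7	degradation
O08557	Ddah1	up	-	0.44	5	283	26	antioxidants
Q9Z1B2	Gstm5	down	-	2.92	6	232	22	antioxidants
Q9Z339	Gsto1	down	-	2.27	6	81	10	antioxidants
Q9Z0V6	Prdx3	down	-	1.87	6	72	8	antioxidants
O35244	Prdx6	down	-	3.75	6	207	18	antioxidants
Q6P7P5	Bzw1	up	-	0.52	4	77	10	biosynthesis
Q4KM73	Cmpk1	up	-	0.55	6	149	10	biosynthesis
Q6P7P5	Bzw1	up	-	0.52	4	77	10	biosynthesis
Q4KM73	Cmpk1	up	-	0.55	6	149	10	biosynthesis
P62630	Eef1a1	up	-	0.44	5	73	10	biosynthesis
Q68FR6	Eef1g	up	-	0.37	6	235	27	biosynthesis
Q5RKI1	Eif4a2	-	down	5.16	5	196	28	biosynthesis
Q32PX7	Fubp1	down	-	1.78	5	97	10	biosynthesis
Q794E4	Hnrnpf	up	-	0.11	4	158	21	biosynthesis
Q6AY09	Hnrnph2	-	up	0.42	5	194	28	biosynthesis
P85973	Pnp	up	-	0.59	6	263	31	biosynthesis
P62716	Ppp2cb	-	down	2.41	4	169	16	biosynthesis
P53042	Ppp5c	down	-	2.37	5	159	18	biosynthesis
F1LPS8	Pura	down	down	1.70	6	73	12	biosynthesis
Q925G0	Rbm3	down	-	1.87	5	73	5	biosynthesis
Q5XIG8	Strap	up	up	0.38	6	141	15	biosynthesis
Q4KM49	Yars	up	up	0.57	5	141	18	biosynthesis
P62961	Ybx1	up	-	0.52	5	219	16	biosynthesis
P97697	Impa1	up	-	0.48	6	214	16	signal transduction
P62260	Ywhae	up	-	0.51	6	213	34	signal transduction
Q64640	Adk	down	-	4.50	6	129	13	regulation
Q02589	Adprh	up	-	0.31	5	111	12	regulation
Q07936	Anxa2	up	-	0.53	6	71	12	regulation
P27139	Ca2	down	-	5.01	6	89	11	regulation
P45592	Cfl1	up	-	0.56	5	154	16	regulation
P08082	Cltb	down	down	2.31	4	104	8	regulation
B0BNE5	Esd	down	-	1.86	5	181	15	regulation
P07936	Gap43	up	-	0.11	6	95	7	regulation
P50399	Gdi2	up	-	0.52	6	311	38	regulation
Q63228	Gmfb	up	-	0.13	6	78	6	regulation
P62749	Hpcal1	down	-	1.96	6	202	17	regulation
O88767	Park7	down	-	1.74	6	280	21	regulation
Q1RP74	Tbcb	up	-	0.32	5	196	17	regulation
P70566	Tmod2	down	-	3.39	6	185	15	regulation
P63029	Tpt1	up	-	0.29	5	135	10	regulation
P11232	Txn	up	-	0.24	6	67	4	regulation
Q920J4	Txnl1	up	-	0.19	4	257	19	regulation
Q6P502	Cct3	-	up	0.33	5	210	31	chaperones
Q68FQ0	Cct5	up	up	0.31	5	329	43	chaperones
P34058	Hsp90ab1	down	down	2.39	6	260	42	chaperones
P06761	Hspa5	down	down	3.49	6	315	34	chaperones
P11598	Pdia3	down	down	1.79	5	73	8	chaperones
B2RYJ7	Actr1b	down	-	1.77	6	173	18	structural
Q4V7C7	Actr3	up	-	0.52	6	230	27	structural
B2GUZ5	Capza1	up	-	0.57	6	230	19	structural
Q5XI32	Capzb	up	-	0.57	6	184	20	structural
P47819	Gfap	down	-	5.72	6	381	48	structural
D4A6B2	Immt	down	-	2.58	6	375	46	structural
P23565	Ina	down	-	1.92	6	391	45	structural
P30009	Marcks	up	-	0.40	6	109	9	structural
P19527	Nefl	down	-	3.49	6	412	53	structural
P12839	Nefm	down	-	2.84	5	291	48	structural
B3GNI6	Sept11	down	down	1.87	5	69	11	structural
P13668	Stmn1	up	-	0.04	6	171	14	structural
Q6AYZ1	Tuba1c	down	-	3.73	4	87	8	structural
Q3KRE8	Tubb2b	up	-	0.48	5	317	42	structural
Q5M7T6	Atp6v0d1	up	-	0.23	5	111	11	transport
Q811Q2	Clic6	down	down	2.43	6	204	19	transport
Q6AYH5	Dctn2	up	-	0.49	4	218	21	transport
Q62871	Dync1i2	down	down	2.13	5	111	11	transport
P55051	Fabp7	up	-	0.21	6	152	12	transport
Q9Z2L0	Vdac1	down	down	2.44	4	215	17	transport
P81155	Vdac2	down	-	2.25	6	168	15	transport
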