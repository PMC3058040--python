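peptide	aq_inh_100	aq_inh_100_sd	aq_inh_500	aq_inh_500_sd	tc_22a1-7E	tc_HCQ.3	tc_HCQ.10	tc_HM1R.2	tc_HD13.9	tc_HNC.1	dr4_inh_100	dr4_inh_100_sd	dr4_inh_500	dr4_inh_500_sd	tc_mDR17.2	tc_hDR11.2
1	90	1	97	0	++++	+++++	++++	++++++	+++++	+++++	39	12	72	4	+++	+++
2	87	1	95	0	++++	+++	+++	+++++	++++	++++	45	5	73	6	++++	++++
3	28	3	59	3	+	+++	+	+++	++	++	41	2	65	4	++++	+++
4	86	1	94	0	+++	+++++	++	+++++	++++	++	8	4	31	10	+++	-
5	29	2	58	2	++	+	+	++	+++	++	49	4	77	1	+++++	++++
6	46	1	75	0	-	-	+	++	-	-	62	2	84	4	+++++	+++
7	39	2	67	1	+	+++	-	+++	++	++	10	14	34	6	+++	-
8	55	3	78	1	+	+	+	+++	-	-	50	1	70	3	+++++	++++
9	38	6	70	1	-	-	-	+	-	-	44	2	75	0	+++++	+++
10	inactive		inactive		n.d.	n.d.	n.d.	n.d.	n.d.	n.d.	20	27	19	15	++	-
11	29	3	53	8	+	+	+	++	+	-	51	5	76	5	+++++	++++
12	inactive		inactive		n.d.	n.d.	n.d.	n.d.	n.d.	n.d.	48	2	73	3	++++	+++
13	inactive		inactive		n.d.	n.d.	n.d.	n.d.	n.d.	n.d.	22	14	52	3	+++	+
14	20	4	50	8	+	+++	+	+++	++	-	46	11	74	1	++++	+++
15	41	1	71	2	-	-	++	++	-	-	55	2	76	2	+++++	++++
16	inactive		inactive		n.d.	n.d.	n.d.	n.d.	n.d.	n.d.	18	22	23	11	+	-
17	inactive		inactive		n.d.	n.d.	n.d.	n.d.	n.d.	n.d.	20	10	26	11	++	-
18	inactive		inactive		n.d.	n.d.	n.d.	n.d.	n.d.	n.d.	47	9	60	6	+++	+++
19	inactive		inactive		n.d.	n.d.	n.d.	n.d.	n.d.	n.d.	37	8	80	5	+++	+++
20	inactive		inactive		n.d.	n.d.	n.d.	n.d.	n.d.	n.d.	62	2	82	3	++++	++
21	inactive		inactive		n.d.	n.d.	n.d.	n.d.	n.d.	n.d.	44	1	84	5	++++	++++
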