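peptide	p260	p263	status
2	Ile	Ffa	confirmed
3	Ile	Tyr	confirmed
4	Ile	Tha	confirmed
5	Hle	Ffa	confirmed
6	Cpa	Cha	confirmed
7	Hle	Tha	confirmed
8	Cpa	Mmp	provisional
9	Chg	Cha	provisional
10	Cpa	Pya	provisional
11	Chg	Mmp	provisional
12	Chg	Tyr	confirmed
13	Ile	Pya	provisional
14	Tha	Phe	confirmed
15	Tha	Mmp	confirmed
16	Hle	Pya	provisional
17	Gln	Tha	provisional
18	Gln	Phe	provisional
19	Gln	Tyr	provisional
20	Aic	Cha	provisional
21	Aic	Ffa	provisional
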