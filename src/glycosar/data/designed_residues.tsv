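position	code	name	natural
p260	Ile	isoleucine	True
p260	Hle	homoleucine	False
p260	Chg	cyclohexylglycine	False
p260	Cpa	cyclopropylalanine	False
p260	Tha	4-thiazolylalanine	False
p260	Gln	glutamine	True
p260	Aic	2-aminoindane-2-carboxylic acid	False
p263	Phe	phenylalanine	True
p263	Ffa	4-fluorophenylalanine	False
p263	Mmp	m-methylphenylalanine	False
p263	Cha	3-cyclohexylalanine	False
p263	Tyr	tyrosine	True
p263	Pya	4-pyridylalanine	False
p263	Tha	4-thiazolylalanine	False
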