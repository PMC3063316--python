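tissue	chrom	strand	position	fdr_corrected_p	gene
adipose tissue	chr8	-	117738703	0.000197	EIF3H
adipose tissue	chr5	+	150017483	0.007937	SYNPO
tonsil	chr6	+	52466294	0.002747	EFHC1
tonsil	chr6	+	52466305	0.002747	
tonsil	chr6	+	52466312	0.002747	
tonsil	chr6	+	52466320	0.002747	
tonsil	chr6	+	52466321	0.002747	
tonsil	chr6	+	52466350	0.002747	
tonsil	chr6	+	52466400	0.002747	
tonsil	chr6	+	52466401	0.002747	
trachea	chr3	-	150569793	0.000233	TM4SF1
thyroid	chr8	-	11737640	0.001768	CTSB
salivary gland	chr15	+	39384948	0.010084	
pituitary gland	chr4	+	57021844	0.015649	PAICS
pancreas	chr15	-	40622466	0.000206	LRRC57
pancreas	chr15	-	40622469	0.000206	
ovary	chrX	-	128767292	7.79e-008	ZDHHC9
nerve	chr8	-	143850023	0.000153	LYNX1
nerve	chr14	-	105401091	0.000609	
ear	chr5	-	81607256	0.000206	RPS23
connective tissue	chr10	-	44192920	0.001107	CXCL12
brain	chr4	+	57021835	5.43e-006	PAICS
blood	chr8	-	145130527	0.001287	PARP10
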