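# Canonical adduct dictionary: label, charge, multiplier, composition, total mass shift (Da).
canonical	charge	multiplier	composition	mass_shift
[M+H]+	1	1	+H	1.00727645
[M+Na]+	1	1	+Na	22.98922070
[M+K]+	1	1	+K	38.96315810
[M+NH4]+	1	1	+NH4	18.03382555
[M+Li]+	1	1	+Li	7.01545597
[M+H-H2O]+	1	1	+H-H2O	-17.00328823
[M+H-2H2O]+	1	1	+H-2H2O	-35.01385292
[M+H-NH3]+	1	1	+H-NH3	-16.01927265
[M+H-CH3OH]+	1	1	+H-CH3OH	-31.01893830
[M+H+ACN]+	1	1	+H+ACN	42.03382555
[M+ACN+Na]+	1	1	+ACN+Na	64.01576980
[M+H+2ACN]+	1	1	+H+2ACN	83.06037465
[M+H+CH3OH]+	1	1	+H+CH3OH	33.03349120
[M+H+IsoProp]+	1	1	+H+IsoProp	61.06479133
[M+H+DMSO]+	1	1	+H+DMSO	79.02121226
[M+2Na-H]+	1	1	+2Na-H	44.97116495
[M+2K-H]+	1	1	+2K-H	76.91903975
[M+H+HCOOH]+	1	1	+H+HCOOH	47.01275576
[M+H+CH3COOH]+	1	1	+H+CH3COOH	61.02840582
[M+ACN+NH4]+	1	1	+ACN+NH4	59.06037465
[M+H+H2O]+	1	1	+H+H2O	19.01784114
[M+2H]2+	2	1	+2H	2.01455290
[M+3H]3+	3	1	+3H	3.02182936
[M+H+Na]2+	2	1	+H+Na	23.99649715
[M+H+K]2+	2	1	+H+K	39.97043455
[M+H+NH4]2+	2	1	+H+NH4	19.04110201
[M+2Na]2+	2	1	+2Na	45.97844140
[M+2H+ACN]2+	2	1	+2H+ACN	43.04110201
[2M+H]+	1	2	+H	1.00727645
[2M+Na]+	1	2	+Na	22.98922070
[2M+K]+	1	2	+K	38.96315810
[2M+NH4]+	1	2	+NH4	18.03382555
[2M+H+ACN]+	1	2	+H+ACN	42.03382555
[2M+H-H2O]+	1	2	+H-H2O	-17.00328823
[3M+H]+	1	3	+H	1.00727645
[3M+Na]+	1	3	+Na	22.98922070
[M-H]-	-1	1	-H	-1.00727645
[M-H-H2O]-	-1	1	-H-H2O	-19.01784114
[M-H-CO2]-	-1	1	-H-CO2	-44.99710569
[M-H-CH3]-	-1	1	-H-CH3	-16.03075155
[M-H-NH3]-	-1	1	-H-NH3	-18.03382555
[M+Cl]-	-1	1	+Cl	34.96940126
[M+Br]-	-1	1	+Br	78.91888568
[M+F]-	-1	1	+F	18.99895180
[M+I]-	-1	1	+I	126.90502158
[M+HCOO]-	-1	1	+HCOO	44.99820285
[M+CH3COO]-	-1	1	+CH3COO	59.01385292
[M+HCOO-H2O]-	-1	1	+HCOO-H2O	26.98763817
[M+TFA-H]-	-1	1	+TFA-H	112.98558748
[M+Na-2H]-	-1	1	+Na-2H	20.97466780
[M+K-2H]-	-1	1	+K-2H	36.94860520
[M+HCOOH-H]-	-1	1	+HCOOH-H	44.99820285
[M+CH3COOH-H]-	-1	1	+CH3COOH-H	59.01385292
[M-2H]2-	-2	1	-2H	-2.01455290
[M-3H]3-	-3	1	-3H	-3.02182936
[M-2H-H2O]2-	-2	1	-2H-H2O	-20.02511759
[2M-H]-	-1	2	-H	-1.00727645
[2M+HCOO]-	-1	2	+HCOO	44.99820285
[2M+CH3COO]-	-1	2	+CH3COO	59.01385292
[3M-H]-	-1	3	-H	-1.00727645
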