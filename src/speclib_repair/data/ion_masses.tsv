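# Neutral-fragment monoisotopic masses (Da) for adduct arithmetic.
# The electron mass is handled separately (one per unit charge).
# Users may extend this table; tokens are matched longest-first.
token	mass
H	1.00782503207
Na	22.9897692809
K	38.96370668
Li	7.01600455
NH4	18.03437413308
NH3	17.02654910101
H2O	18.01056468374
Cl	34.96885268
Br	78.9183371
I	126.904473
F	18.99840322
HCOO	44.99765427127
HCOOH	46.00547930334
CH3COO	59.01330433541
CH3COOH	60.02112936748
CH3OH	32.02621474788
ACN	41.02654910101
CH3	15.02347509621
CO2	43.9898292392
CO	27.9949146196
DMSO	78.01393581202
IsoProp	60.05751487616
TFA	113.99286393127
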