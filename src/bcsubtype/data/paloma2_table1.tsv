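# Cross-classification of intrinsic subtype calls, advanced-breast-cancer trial (n = 222).
# Rows: gene-pair rule classifier on the targeted expression panel (HTG-AIMS).
# Columns: clinical four-subtype centroid assay (ruoProsigna-PAM50).
rules\centroid	BL	HER2-E	LumA	LumB
BL	1	0	0	0
HER2-E	6	6	6	13
LumA	0	2	60	56
LumB	2	12	3	52
NL	0	0	3	0
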