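# Cross-classification of intrinsic subtype calls, neoadjuvant trial (n = 224).
# Rows: gene-pair rule classifier on whole-transcriptome RNA-seq (RNAseq-AIMS).
# Columns: PAM50 with subgroup-median centering + technical calibration (RNAseq-PAM50.sgMd.TC).
rules\centroid	BL	HER2-E	LumA	LumB	NL
BL	3	0	0	0	1
HER2-E	1	3	8	6	1
LumA	0	0	97	2	0
LumB	0	0	26	41	0
NL	0	0	25	0	10
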