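# receptor = ER
# cutoff = 0.43
# source = published 24-gene ER signature (35 probe sets); coefficients as printed, probe IDs are gene-symbol placeholders (synthetic) except 205225_at (ESR1), the one ID named in the text
probe_id	rho
ADCY9	0.44
AMFR	0.44
ANXA9	0.43
ANXA9_2	0.45
C6orf97	0.45
CA12	0.48
CA12_2	0.48
CA12_3	0.47
CA12_4	0.47
CA12_5	0.47
CELSR1	0.43
CYP2B6_CYP2B7P1	0.45
205225_at	0.50
FAM176B	0.46
FAM176B_2	0.43
GAMT	0.45
GATA3	0.45
GATA3_2	0.48
GATA3_3	0.47
GFRA1	0.45
GREB1	0.46
IL6ST	0.44
IL6ST_2	0.44
KCNK15	0.44
KDM4B	0.45
KDM4B_2	0.46
KDM4B_3	0.43
SCCPDH	0.43
SCUBE2	0.46
LIV1	0.46
SSH3	0.44
STC2	0.44
TBC1D9	0.43
TFF1	0.44
UNKNOWN	0.45
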