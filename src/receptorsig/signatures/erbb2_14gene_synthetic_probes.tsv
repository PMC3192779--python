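# receptor = ERBB2
# cutoff = 0.35
# source = published 14-gene ERBB2 signature (19 probe sets); coefficients as printed, probe IDs are gene-symbol placeholders (synthetic) except 203497_at (PPARBP), the one ID named in the text
probe_id	rho
CRK7	0.38
ERBB2	0.42
ERBB2_2	0.39
F2RL1	0.35
GRB7	0.43
IDI1	0.37
ITGB6	0.36
ITGB6_2	0.35
PERLD1	0.37
PERLD1_2	0.38
203497_at	0.45
PPARBP_2	0.39
SEC63	0.37
STARD3	0.37
TRIM26	0.36
DIRAS2	-0.36
DUSP24	-0.36
UBTF	-0.36
UNKNOWN	-0.37
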