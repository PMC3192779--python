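# receptor = PR
# cutoff = 0.38
# source = published 51-gene PR signature (61 probe sets); coefficients as printed, probe IDs are gene-symbol placeholders (synthetic) except 219197_s_at (SCUBE2), the one ID named in the text
probe_id	rho
BBS1	0.40
BBS1_2	0.40
BCAM	0.40
CA12	0.39
CA12_2	0.40
CASC1	0.39
FAM176B	0.41
FAM176B_2	0.44
GAMT	0.40
GATA3	0.39
GATA3_2	0.41
GFRA1	0.39
GLI3	0.39
HPN	0.39
IL6ST	0.40
IL6ST_2	0.41
KDM4B	0.41
KDM4B_2	0.42
LAMB2	0.40
LRRC17	0.39
LZTFL1	0.39
MAGED2	0.39
MAPT	0.39
MAPT_2	0.40
PDE4A	0.38
PGR	0.41
219197_s_at	0.44
LIV1	0.38
STARD13	0.39
STC2	0.38
WDR19	0.40
UNKNOWN	0.40
AURKA	-0.40
AURKA_2	-0.38
BUB1	-0.41
C16orf61	-0.38
CCNA2	-0.40
CDC20	-0.40
CDCA8	-0.39
CENPA	-0.38
CENPN	-0.38
CEP55	-0.39
DBF4	-0.44
DDX39	-0.39
DLGAP5	-0.39
GATAD2A	-0.41
GTSE1	-0.38
HJURP	-0.39
KIF2C	-0.41
KIF2C_2	-0.41
KPNA2	-0.41
LAD1	-0.41
LPIN1	-0.40
MCAM	-0.39
MELK	-0.40
MKI67	-0.39
OR7E37P	-0.39
PSME4	-0.42
PTTG1	-0.40
SLC7A5	-0.40
TTK	-0.40
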