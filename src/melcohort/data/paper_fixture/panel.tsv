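gene	tumor_gene
ALK	false
ARID1B	false
ARID2	true
BAP1	true
BRAF	true
CCND2	true
CCND3	true
CDK4	true
CDKN2A	true
CHEK2	true
CTNNB1	true
EGFR	true
ERBB2	true
ERBB3	true
FAT1	false
FGFR2	false
GNA11	true
GNAQ	true
GRIN2A	false
HRAS	true
JAK2	true
KIT	true
KMT2D	false
KRAS	true
LRP1B	false
MDM2	true
MET	true
MYC	true
NF1	true
NOTCH2	false
NRAS	true
PDGFRA	true
PREX2	false
PTEN	true
PTPRD	true
RET	false
RICTOR	true
ROS1	false
SF3B1	true
SMARCA4	true
SPEN	false
TP53	true
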