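# Genes whose skeletal-muscle (m. vastus lateralis) expression changes
# significantly (p < 0.05) after a single bout of resistance exercise,
# from a published 7-subject transcriptome dataset: 10 upregulated and
# 16 downregulated genes.
# Note: the source's downregulated list prints "TRIB1 WWP2" as one merged
# token while stating 16 genes; it is transcribed here as the two gene
# symbols TRIB1 and WWP2, which restores the stated count.
gene	exercise_response
ADCY3	up
E2F3	up
JMJD1C	up
JUND	up
MLN	up
MYO1C	up
PIEZO1	up
PPARD	up
SFMBT1	up
ZNF462	up
CDKAL1	down
CEP192	down
DLEU1	down
GADD45G	down
GBF1	down
GLCCI1	down
MAML3	down
MMS22L	down
NYAP2	down
SDCCAG8	down
SWT1	down
TRIB1	down
WWP2	down
XPO4	down
ZBTB38	down
ZNF420	down
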