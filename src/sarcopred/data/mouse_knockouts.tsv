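# Mouse knockout effects on lean mass / grip strength (IMPC-style lookup)
# and human eQTL direction of the protective allele on the gene's expression.
# knockout_direction: -1 = knockout decreases lean mass and strength,
# +1 = knockout increases lean mass and strength, . = tested but no
# significant effect. expression_direction: +1 = protective allele raises
# expression, -1 = lowers it, . = unknown/not an eQTL hit.
# The 8 rows with knockout_direction '.' are SYNTHETIC placeholders: they
# stand in for the tested-but-not-significant knockouts, whose identities
# are not published; only the tested/significant tallies depend on them.
gene	knockout_tested	knockout_direction	expression_direction
ADCY3	yes	-1	+1
AOC1	yes	-1	.
BCKDHB	yes	-1	+1
BTNL2	yes	-1	.
CDKAL1	yes	-1	.
CEP192	yes	-1	+1
GDF5	yes	-1	.
H1FX	yes	-1	+1
POLD3	yes	-1	+1
RBL2	yes	-1	.
SWT1	yes	-1	.
ZNF462	yes	-1	.
ADPGK	yes	+1	.
BTRC	yes	+1	-1
CAMKMT	yes	+1	.
DIPK1A	yes	+1	.
E2F3	yes	+1	.
FOXP1	yes	+1	.
HTT	yes	+1	.
IGF2BP3	yes	+1	.
JMJD1C	yes	+1	.
LCORL	yes	+1	-1
MLLT10	yes	+1	.
MTCH2	yes	+1	-1
NCOA1	yes	+1	.
PIEZO1	yes	+1	.
TRIB1	yes	+1	.
DLEU1	yes	.	.
SLC39A8	yes	.	.
HMGA2	yes	.	.
WWP2	yes	.	.
KIF1B	yes	.	.
SOX5	yes	.	.
PPARD	yes	.	.
GBF1	yes	.	.
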