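# Pleiotropic sarcopenia-predictor variants: per-variant protective/risk
# alleles and p-values against handgrip strength, appendicular lean mass,
# usual walking pace, body fat percentage and type 2 diabetes.
# NS = not significant (p > 0.005). p-values are kept as printed.
gene	rsid	protective_allele	risk_allele	p_grip	p_lean	p_walk	p_fat	p_t2d
GDF5	rs143384	G	A	5.5e-46	7.0e-319	4.0e-8	NS	NS
POLD3	rs72977282	T	A	7.4e-28	9.3e-8	3.6e-3	NS	NS
LCORL	rs1472852	C	A	4.0e-24	8.2e-135	3.7e-4	3.0e-5	NS
ADCY3	rs10203386	T	A	1.6e-23	1.7e-36	3.3e-3	2.4e-38	NS
DLEU1	rs3116602	T	G	1.4e-21	9.5e-155	8.7e-4	NS	NS
AOC1	rs6977416	A	G	6.7e-19	1.4e-113	7.7e-4	5.6e-10	NS
SLC39A8	rs13107325	C	T	2.0e-17	3.9e-3	1.8e-21	5.0e-23	1.1e-4
HLA-DRB1	rs34415150	A	G	3.4e-17	2.5e-17	2.3e-5	6.6e-4	6.0e-17
HLA-DRB1	rs2760975	G	A	4.6e-17	1.7e-17	1.6e-5	8.4e-6	6.9e-10
MLLT10	rs1243182	C	T	3.5e-16	2.6e-3	3.9e-7	6.5e-14	NS
PRRC2A	rs2260051	A	T	1.0e-15	5.2e-6	2.6e-5	3.3e-17	1.7e-13
BTNL2	rs2213581	T	C	1.1e-15	4.3e-20	6.3e-4	3.3e-6	3.2e-11
FKBPL	rs41268905	G	A	2.4e-15	8.9e-17	4.0e-4	1.3e-5	NS
ZBTB38	rs2871960	C	A	4.0e-15	2.2e-135	1.0e-3	NS	9.5e-5
ADCY3	rs1056074	T	C	7.6e-15	1.2e-11	1.3e-3	1.8e-17	NS
PML	rs5742915	C	T	1.8e-14	9.3e-39	4.0e-5	4.1e-8	1.6e-3
POU6F2	rs4549685	T	C	4.5e-14	4.0e-7	7.3e-5	2.1e-12	1.5e-4
HMGA2	rs4338565	C	T	8.0e-14	4.9e-151	2.3e-4	NS	1.4e-3
HLA-DRB1	rs113315602	A	C	1.4e-12	1.0e-5	5.4e-4	3.5e-6	NS
WWP2	rs4985445	A	G	1.4e-12	3.3e-20	1.2e-5	4.6e-18	1.7e-5
MTCH2	rs11039324	G	A	3.5e-12	7.3e-26	3.9e-15	9.0e-38	3.2e-6
HLA-DRB5	rs117108573	C	T	3.6e-11	1.1e-4	7.4e-4	3.4e-4	NS
GBF1	rs2273555	G	A	4.1e-11	8.1e-5	8.2e-5	NS	NS
SFMBT1	rs62253653	G	A	9.5e-11	3.0e-3	1.0e-7	4.0e-3	1.2e-3
JARID2	rs2237149	A	C	7.5e-10	4.5e-5	1.8e-4	6.4e-6	NS
ADPGK	rs4776614	C	G	1.9e-9	8.4e-6	1.4e-4	5.6e-13	NS
JUND	rs7249	T	C	2.0e-9	1.2e-6	2.6e-4	5.8e-13	NS
KIF1B	rs3903151	G	A	2.6e-9	1.3e-16	3.0e-4	1.2e-4	2.9e-3
SWT1	rs10797999	T	C	3.0e-9	1.4e-5	1.4e-8	2.5e-4	NS
FOXP1	rs4677611	T	C	3.2e-9	2.4e-4	2.2e-3	2.3e-5	NS
SOX5	rs11047225	C	T	8.5e-9	4.3e-10	2.2e-3	NS	NS
NCOA1	rs77012907	A	G	1.2e-8	1.2e-13	5.8e-4	2.9e-15	NS
MMS22L	rs9320823	T	C	1.4e-8	7.9e-10	1.1e-6	3.9e-22	1.5e-4
ZKSCAN5	rs3843540	C	T	2.3e-8	5.8e-6	1.1e-4	4.0e-9	NS
MLN	rs12055409	G	A	3.5e-8	3.6e-3	1.8e-3	3.2e-7	4.4e-4
FOXP1	rs830643	A	G	4.0e-8	9.7e-7	2.9e-7	5.7e-8	9.3e-6
GADD45G	rs1329733	A	G	4.3e-8	2.2e-4	6.4e-5	9.0e-13	NS
IL11	rs4252548	C	T	6.2e-8	4.8e-35	2.6e-3	NS	NS
COMMD4	rs11636600	G	A	6.8e-8	5.0e-13	9.7e-11	NS	NS
HABP4	rs6477489	C	A	7.2e-8	5.2e-59	3.7e-3	1.1e-3	NS
GLCCI1	rs12702693	T	C	1.8e-7	6.6e-20	1.4e-3	NS	NS
H1FX	rs4073154	G	A	2.5e-7	1.9e-33	3.3e-8	NS	NS
CEP192	rs1786263	G	T	3.1e-7	1.0e-22	2.3e-3	5.5e-7	NS
PPARD	rs3734254	T	C	5.2e-7	2.3e-33	5.6e-6	NS	NS
ZNF568	rs1667369	A	C	1.3e-6	1.5e-10	2.7e-8	1.7e-3	NS
SERPINA1	rs28929474	T	C	3.5e-6	1.1e-14	3.4e-4	NS	2.6e-3
NMT1	rs2301597	C	T	4.6e-6	4.8e-33	2.7e-9	1.3e-8	NS
PIEZO1	rs2968478	T	G	5.1e-6	5.6e-14	2.8e-3	NS	NS
CELF4	rs12962050	A	G	6.8e-6	1.5e-14	4.8e-4	2.1e-3	NS
BCKDHB	rs9350850	C	T	7.5e-6	2.9e-24	1.3e-3	NS	NS
E2F3	rs4134943	T	C	9.9e-6	2.0e-8	4.9e-9	6.7e-5	1.2e-5
BTRC	rs10883618	A	G	2.6e-5	1.8e-4	4.1e-9	1.5e-6	4.6e-3
LIN28A	rs4274112	A	G	2.8e-5	2.5e-28	8.5e-4	6.8e-4	3.3e-4
ZNF420	rs62108897	C	A	6.3e-5	7.7e-19	4.7e-3	7.1e-4	NS
JUND	rs10686842	TAAA	T	6.4e-5	7.4e-24	3.7e-4	1.6e-19	NS
DIPK1A	rs12733767	C	T	6.8e-5	9.4e-14	9.0e-5	3.2e-3	NS
IGF2BP3	rs34776209	C	T	6.9e-5	1.8e-47	8.4e-4	NS	NS
XPO4	rs7321635	A	C	9.0e-5	2.6e-11	4.5e-4	NS	NS
FHL2	rs55680124	C	T	1.1e-4	4.2e-4	2.6e-9	6.0e-8	2.3e-7
VCAN	rs115912456	G	A	1.8e-4	3.7e-34	1.8e-3	3.5e-14	NS
RBL2	rs72801843	A	T	1.9e-4	8.8e-52	8.9e-6	NS	4.5e-5
NPPC	rs73000823	C	T	2.3e-4	1.7e-15	3.7e-4	1.4e-5	NS
MYO1C	rs9905106	T	C	3.5e-4	7.5e-14	3.9e-3	4.4e-5	NS
CDKAL1	rs745771286	G	GA	3.9e-4	2.7e-11	4.8e-5	4.7e-5	NS
GIP	rs4794005	A	G	4.3e-4	8.8e-15	1.1e-3	4.9e-4	3.6e-4
NCL	rs10202701	T	C	4.3e-4	3.1e-33	2.0e-3	2.3e-5	NS
SOCS5	rs62136933	A	G	5.7e-4	9.0e-32	2.1e-4	3.8e-11	NS
CAMKMT	rs11893991	A	G	6.0e-4	2.3e-9	2.4e-3	NS	NS
RIN3	rs117068593	T	C	6.0e-4	8.8e-62	3.9e-3	3.8e-10	NS
JMJD1C	rs7924036	T	G	8.9e-4	1.2e-5	1.2e-13	NS	NS
TRIB1	rs4870941	G	C	1.3e-3	1.1e-39	2.1e-3	NS	NS
SDCCAG8	rs2994330	T	G	2.4e-3	6.6e-12	9.6e-5	3.0e-4	NS
NYAP2	rs2054079	T	C	3.0e-3	3.9e-4	4.3e-9	NS	NS
MAML3	rs57800857	C	A	3.5e-3	4.0e-7	6.4e-11	1.4e-13	2.7e-4
PITX1	rs4976261	G	C	3.6e-3	8.7e-43	1.7e-3	NS	NS
PKDCC	rs3035165	T	TTA	3.7e-3	6.9e-14	1.0e-3	3.0e-8	NS
HTT	rs362307	C	T	3.9e-3	2.5e-7	1.1e-9	2.8e-9	1.3e-6
ZNF462	rs902144	C	G	4.0e-3	7.2e-13	4.0e-4	1.7e-3	NS
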