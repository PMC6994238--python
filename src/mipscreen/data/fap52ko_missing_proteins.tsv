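name	mw_kda	p_value	wt_peptides	wt_values
ARL3	20	0.0013	2,2,1	2,1,2
CHLREDRAFT_171815	57	0.035	2,6,1	2,5,2
CHLREDRAFT_156073	11	0.024	1,1,1	2,1,2
FAP276	10	0.015	3,3,2	8,7,14
FAP52	66	0.0046	27,21,15	59,73,105
FAP36	41	0.0023	3,3,1	3,3,2
CrCDPK1	54	0.0001	3,5,2	3,4,4
CHLREDRAFT_176830	110	0.024	2,1,2	2,1,1
FAP173	33	0.012	3,3,1	5,3,2
FAP29	112	0.00045	2,3,2	3,3,4
CHLREDRAFT_181390	41	0.028	1,1,1	1,1,2
ANK2	60	0.0041	1,2,1	1,1,2
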