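name	mw_kda	aqv	rspa_printed	homolog_tetrahymena	homolog_human	localization
TUA1	50	1077.97	215.59	TBA_TETTH	TUBA1C	Doublet
TUB1	50	625.46	125.09	TBB_TETTH	TUBB4B	Doublet
RIB72	72	116.72	16.21	TTHERM_00143690	EFHC1	MIP
PACRG	25	38.39	15.35	TTHERM_00446290	PACRG	IJ
PF16	50	74.09	14.82	TTHERM_000157929	SPAG6	Central Pair
RSP9	30	41.79	13.93	TTHERM_00430020	RSPH9	Radial Spoke
FAP86	30	36.11	12.04	-	-	Doublet
FAP1	22	26.46	12.03	-	-	Doublet
FAP52	66	79.12	11.99	TTHERM_01094880	CFAP52	MIP
FAP20	22	26.08	11.86	TTHERM_00418580	CFAP20	IJ
FAP126	15	16.89	11.26	-	CFAP126	MIP
RSP1	88	98.73	11.22	TTHERM_00047490	RSPH1	Radial Spoke
FAP115	27	29.98	11.10	TTHERM_00193760	-	Doublet
FAP106	27	29.81	11.04	TTHERM_00137550	ENKUR	IJ?
Tektin	53	57.61	10.87	-	TEKT5	IJ?
RSP3	57	60.55	10.62	TTHERM_00566810	RSPH3	Radial Spoke
FAP252	39	39.97	10.25	TTHERM_00899430	CETN3	Axonemal
RSP2	77	77.95	10.12	-	CALM2	Radial Spoke
FAP161	43	43.50	10.12	TTHERM_00155380	CFAP161	Axonemal
IDA4	29	27.29	9.41	TTHERM_00841210	DNALI1	Dynein
FAP107	26	23.66	9.10	-	FLG2	Axonemal
DHC2	457	414.12	9.06	TTHERM_01027670	DNAH1	Dynein
FAP12	54	48.85	9.05	-	DAGLB	Cytoplasmic
RSP7	34	30.62	9.01	TTHERM_00194419	CALML5	Radial Spoke
RSP5	56	49.32	8.81	-	-	Radial Spoke
FAP230	45	39.59	8.80	-	-	Axonemal
FAP77	29	23.88	8.24	TTHERM_00974270	CFAP77	Axonemal
FAP55	111	90.47	8.15	-	MYH14	Axonemal
FAP90	28	22.35	7.98	-	WBP11	Axonemal
RSP10	24	19.10	7.96	TTHERM_00378600	RSPH1	Radial Spoke
FAP71	32	24.86	7.77	TTHERM_00077710	EWSR1	Axonemal
EEF1	51	39.04	7.66	TTHERM_00655820	Multiple	Axonemal
FAP182	49	36.69	7.49	TTHERM_01049330	C9orf116	Axonemal
Rib43a	43	32.06	7.46	TTHERM_00624660	RIBC2	MIP
FAP45	59	43.20	7.32	TTHERM_001164064	CFAP45	MIP
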