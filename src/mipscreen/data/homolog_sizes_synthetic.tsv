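protein_id	species	homolog_id	homolog_mw_kda
FAP115	T. thermophila	TTHERM_00193760	107.0
FAP106	T. thermophila	TTHERM_00137550	28.0
FAP252	T. thermophila	TTHERM_00899430	40.0
FAP161	T. thermophila	TTHERM_00155380	154.0
FAP77	T. thermophila	TTHERM_00974270	31.0
FAP71	T. thermophila	TTHERM_00077710	35.0
EEF1	T. thermophila	TTHERM_00655820	52.0
FAP182	T. thermophila	TTHERM_01049330	50.0
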