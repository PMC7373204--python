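taxon	group	n_genes	pct_missing	pct_gc
Chlorella_vulgaris	Chlorophyta	65	21.28	38.24
Chlamydomonas_reinhardtii	Chlorophyta	57	32.39	36.30
Ostreococcus_tauri	Chlorophyta	54	35.56	42.02
Nephroselmis_olivacea	Chlorophyta	74	4.81	43.13
Mesostigma_viride	Streptophyta	79	3.55	33.57
Chlorokybus_atmophyticus	Streptophyta	81	1.66	37.96
Klebsormidium_flaccidum	Streptophyta	73	7.23	43.33
Chara_vulgaris	Streptophyta	81	1.34	34.63
Chaetosphaeridium_globosum	Streptophyta	83	0.09	33.77
Staurastrum_punctulatum	Streptophyta	81	1.22	35.77
Zygnema_circumcarinatum	Streptophyta	81	0.90	37.93
Mesotaenium_endlicherianum	Streptophyta	81	0.74	44.29
Roya_anglica	Streptophyta	81	0.47	36.63
Pellia_endiviifolia	Streptophyta	82	0.50	38.24
Ptilidium_pulcherrimum	Streptophyta	77	10.7	35.72
Physcomitrella_patens	Streptophyta	80	2.84	33.46
Syntrichia_ruralis	Streptophyta	77	9.90	33.21
Nothoceros_aenigmaticus	Streptophyta	81	2.80	39.10
Anthoceros_formosae	Streptophyta	81	1.92	37.31
Isoetes_flaccida	Streptophyta	79	3.83	40.75
Huperzia_lucidula	Streptophyta	83	0.03	38.98
Selaginella_moellendorffii	Streptophyta	66	10.12	50.77
Equisetum_hyemale	Streptophyta	81	0.52	36.02
Psilotum_nudum	Streptophyta	79	7.68	38.57
Angiopteris_evecta	Streptophyta	83	0.01	38.01
Adiantum_capillus-veneris	Streptophyta	79	7.31	43.42
Pinus_thunbergii	Streptophyta	69	20.61	40.65
Cycas_revoluta	Streptophyta	81	1.08	40.72
Arabidopsis_thaliana	Streptophyta	76	8.70	39.04
Nymphaea_alba	Streptophyta	77	8.20	41.01
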