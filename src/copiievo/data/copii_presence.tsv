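taxon	Sar1	Sec12	Sec16	Sec23	Sec24	Sec13	Sec31	Sed4
Homo_sapiens	1	1	1	1	1	1	1	0
Saccharomyces_cerevisiae	1	1	1	1	1	1	1	1
Saccharomyces_paradoxus	1	1	1	1	1	1	1	1
Saccharomyces_mikatae	1	1	1	1	1	1	1	1
Saccharomyces_bayanus	1	1	1	1	1	1	1	1
Candida_glabrata	1	1	1	1	1	1	1	1
Encephalitozoon_cuniculi	1	0	0	1	1	1	1	0
Nosema_ceranae	1	0	0	1	1	1	1	0
Fonticula_alba	1	0	0	1	1	1	1	0
Entamoeba_histolytica	1	0	0	1	1	1	1	0
Dictyostelium_discoideum	1	1	1	1	1	1	1	0
Acanthamoeba_castellanii	1	1	1	1	1	1	1	0
Arabidopsis_thaliana	1	1	1	1	U	1	1	0
Chlamydomonas_reinhardtii	1	1	1	1	1	1	1	0
Cyanidioschyzon_merolae	1	0	0	1	1	1	1	0
Phytophthora_sojae	1	1	1	1	U	1	1	0
Nannochloropsis_gaditana	1	0	0	1	1	1	1	0
Tetrahymena_thermophila	1	1	1	1	1	1	1	0
Reticulomyxa_filosa	1	0	0	1	1	1	1	0
Trypanosoma_brucei	1	1	1	1	1	1	1	0
Naegleria_gruberi	1	1	1	1	1	1	1	0
Giardia_lamblia	1	0	0	1	1	1	1	0
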