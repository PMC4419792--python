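(((Homo_sapiens,((((Saccharomyces_cerevisiae,(Saccharomyces_paradoxus,(Saccharomyces_mikatae,Saccharomyces_bayanus))Saccharomyces)Saccharomyces_crown,Candida_glabrata)Sacch_Cgla,(Encephalitozoon_cuniculi,Nosema_ceranae)Microsporidia)Fungi,Fonticula_alba)Holomycota)Opisthokonta,((Entamoeba_histolytica,Dictyostelium_discoideum)Evosea,Acanthamoeba_castellanii)Amoebozoa)Amorphea,(((Arabidopsis_thaliana,Chlamydomonas_reinhardtii)Viridiplantae,Cyanidioschyzon_merolae)Archaeplastida,(((Phytophthora_sojae,Nannochloropsis_gaditana)Stramenopiles,(Tetrahymena_thermophila,Reticulomyxa_filosa)Alveolata_Rhizaria)SAR_CCTH,((Trypanosoma_brucei,Naegleria_gruberi)Discoba,Giardia_lamblia)Excavata)SAR_Excavata)Diaphoretickes)LECA;
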