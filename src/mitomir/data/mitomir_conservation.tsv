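mirna_id	species	order
hsa-miR-1973	Hsa	Primates
hsa-miR-1275	Hsa	Primates
hsa-miR-1275	Ptr	Primates
hsa-miR-1275	Ppy	Primates
hsa-miR-494	Hsa	Primates
hsa-miR-494	Ptr	Primates
hsa-miR-494	Ppy	Primates
hsa-miR-494	Mml	Primates
hsa-miR-494	Mmu	Glires
hsa-miR-494	Rno	Glires
hsa-miR-494	Cfa	Carnivora
hsa-miR-494	Eca	Perissodactyla
hsa-miR-494	Bta	Perissodactyla
hsa-miR-494	Ssc	Cetertiodactyla
hsa-miR-513a	Hsa	Primates
hsa-miR-513a	Ptr	Primates
hsa-miR-513a	Ppy	Primates
hsa-miR-513a	Mml	Primates
hsa-miR-513a	Age	Primates
hsa-miR-513a	Ssy	Primates
hsa-miR-513a	Pbi	Primates
hsa-miR-1246	Hsa	Primates
hsa-miR-1246	Ptr	Primates
hsa-miR-1246	Ppy	Primates
hsa-miR-328	Hsa	Primates
hsa-miR-328	Ptr	Primates
hsa-miR-328	Ppy	Primates
hsa-miR-328	Mmu	Glires
hsa-miR-328	Rno	Glires
hsa-miR-328	Cfa	Carnivora
hsa-miR-328	Eca	Perissodactyla
hsa-miR-328	Bta	Perissodactyla
hsa-miR-328	Ssc	Cetertiodactyla
hsa-miR-1908	Hsa	Primates
hsa-miR-1908	Ppy	Primates
hsa-miR-1972	Hsa	Primates
hsa-miR-1974	Hsa	Primates
hsa-miR-1977	Hsa	Primates
hsa-miR-638	Hsa	Primates
hsa-miR-638	Ppy	Primates
hsa-miR-638	Mml	Primates
hsa-miR-1978	Hsa	Primates
hsa-miR-1201	Hsa	Primates
hsa-miR-1201	Ptr	Primates
hsa-miR-1201	Ppy	Primates
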