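# Miniature taxon -> functional-group rules (rank:Name<TAB>group).
# A deliberately small rules file covering the biogeochemical functions the
# pipeline reports on; not a substitute for a curated trait database.
genus:Desulfovibrio	sulfate_respiration
family:Desulfovibrionaceae	sulfate_respiration
genus:Geobacter	iron_respiration
genus:Desulfovibrio	iron_respiration
genus:Nostoc	nitrogen_fixation
genus:Bradyrhizobium	nitrogen_fixation
phylum:Cyanobacteria	phototrophy
genus:Halocella	cellulolysis
genus:Anaerolinea	cellulolysis
genus:Methanobacterium	dark_hydrogen_oxidation
genus:Methanosarcina	dark_hydrogen_oxidation
genus:Methanosarcina	methanogenesis
genus:Methanobacterium	methanogenesis
genus:Nitrososphaera	nitrification
genus:Nitrososphaera	aerobic_ammonia_oxidation
genus:Bacillus	fermentation
genus:Halocella	fermentation
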