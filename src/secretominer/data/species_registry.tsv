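name	lifestyle	phylum	family
Agaricus bisporus	Litter decayers	Basidiomycota	Agaricacae
Amanita thiersii	Litter decayers	Basidiomycota	Amanitacae
Amanita muscaria	Ectomycorrhizal	Basidiomycota	Amanitaceae
Plicaturopsis crispa	Brown rot	Basidiomycota	Amylocorticiaceae
Piloderma croceum	Ectomycorrhizal	Basidiomycota	Atheliales
Auricularia subglabra	White rot	Basidiomycota	Auriculariaceae
Heterobasidion annosum	White rot	Basidiomycota	Bondarzewiaceae
Botryobasidium botryosum	Brown rot	Basidiomycota	Botryobasidiaceae
Coniophora puteana	Brown rot	Basidiomycota	Coniophoraceae
Punctularia strigosozonata	White rot	Basidiomycota	Corticiaceae
Hebeloma cylindrosporum	Ectomycorrhizal	Basidiomycota	Cortinariaceae
Dacryopinax sp	Brown rot	Basidiomycota	Dacrymycetaceae
Fomitopsis pinicola	White rot	Basidiomycota	Fomitopsidaceae
Sphaerobolus stellatus	White rot	Basidiomycota	Geastraceae
Gloeophyllum trabeum	Brown rot	Basidiomycota	Gloeophyllaceae
Fomitiporia mediterranea	White rot	Basidiomycota	Hymenochaetaceae
Jaapia argillacea	Brown rot	Basidiomycota	Jaapiaceae
Melampsora larici-populina	Pathogen	Basidiomycota	Melampsoraceae
Hydnomerulius pinastri	Brown rot	Basidiomycota	Paxillaceae
Paxillus involutus	Ectomycorrhizal	Basidiomycota	Paxillaceae
Paxillus rubicondulus	Ectomycorrhizal	Basidiomycota	Paxillaceae
Phanerochaete chrysosporium	White rot	Basidiomycota	Phanerochaetaceae
Pleurotus ostreatus	White rot	Basidiomycota	Pleurotaceae
Trametes versicolor	White rot	Basidiomycota	Polyporaceae
Coprinopsis cinerea	Litter decayers	Basidiomycota	Psathyrellaceae
Schizophyllum commune	White rot	Basidiomycota	Schizophyllaceae
Pisolithus tinctorius	Ectomycorrhizal	Basidiomycota	Sclerodermataceae
Pisolithus microcarpus	Ectomycorrhizal	Basidiomycota	Sclerodermataceae
Scleroderma citrinum	Ectomycorrhizal	Basidiomycota	Sclerodermataceae
Sebacina vermifera	Orchid symbiont	Basidiomycota	Sebacinaceae
Piriformospora indica	Endophyte	Basidiomycota	Sebacinaceae
Serpula lacrymans	Brown rot	Basidiomycota	Serpulaceae
Galerina marginata	White rot	Basidiomycota	Strophariaceae
Hypholoma sublateritium	White rot	Basidiomycota	Strophariaceae
Suillus luteus	Ectomycorrhizal	Basidiomycota	Suillaceae
Tremella mesenterica	Mycoparasitic	Basidiomycota	Tremellaceae
Laccaria bicolor	Ectomycorrhizal	Basidiomycota	Tricholomataceae
Gymnopus luxurians	Litter decayers	Basidiomycota	Tricholomatocae
Tulasnella calospora	Orchid symbiont	Basidiomycota	Tulasnellales
Ustilago maydis	Pathogen	Basidiomycota	Ustilaginaceae
Aspergillus nidulans	Litter decayers	Ascomycota	Trichocomaceae
Cryphonectria parasitica	Pathogen	Ascomycota	Cryphonectriaceae
Oidiodendron maius	Ericoid symbiont	Ascomycota	Myxotrichaceae
Pichia stipitis	Yeast	Ascomycota	Saccharomycetaceae
Stagonospora nodorum	Pathogen	Ascomycota	Phaeosphaeriaceae
Trichoderma reesei	Litter decayers	Ascomycota	Hypocreaceae
Tuber melanosporum	Ectomycorrhizal	Ascomycota	Tuberaceae
Batrachochytrium dendrobatidis	Pathogen	Chytridiomycota	Incertae sedis
Phycomyces blakesleeanus	Litter decayers	Zygomycota	Phycomycetaceae
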