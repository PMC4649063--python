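# Explicit map from the abbreviated species names used in the packaged SSP
# cluster table to the full binomials of the species registry. One-letter
# genus initials collide (Paxillus/Pisolithus/Piloderma/Pleurotus/
# Plicaturopsis/Punctularia/Phanerochaete all print as "P."), so resolution
# is by exact lookup in this table, never by prefix matching. Spelling
# variants that appear in the printed table are listed alongside the
# canonical abbreviations.
abbreviation	name
A. bisporus	Agaricus bisporus
A. muscaria	Amanita muscaria
A. muscara	Amanita muscaria
A. thiersii	Amanita thiersii
A. subglabra	Auricularia subglabra
C. cinerea	Coprinopsis cinerea
F. mediterranea	Fomitiporia mediterranea
F. pinicola	Fomitopsis pinicola
G. trabeum	Gloeophyllum trabeum
G. luxurians	Gymnopus luxurians
H. cylindrosporum	Hebeloma cylindrosporum
H. annosum	Heterobasidion annosum
H. sublateritium	Hypholoma sublateritium
H. sublateriutium	Hypholoma sublateritium
J. argillacea	Jaapia argillacea
L. bicolor	Laccaria bicolor
P. involutus	Paxillus involutus
P. rubicondulus	Paxillus rubicondulus
P. chrysosporium	Phanerochaete chrysosporium
P. chrisosporium	Phanerochaete chrysosporium
P. croceum	Piloderma croceum
P. microcarpus	Pisolithus microcarpus
P. tinctorius	Pisolithus tinctorius
P. ostreatus	Pleurotus ostreatus
P. crispa	Plicaturopsis crispa
P. strigosozonata	Punctularia strigosozonata
P. strigozonata	Punctularia strigosozonata
S. commune	Schizophyllum commune
S. citrinum	Scleroderma citrinum
S. lacrymans	Serpula lacrymans
S. luteus	Suillus luteus
Suillus luteus	Suillus luteus
T. versicolor	Trametes versicolor
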