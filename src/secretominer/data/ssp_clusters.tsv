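# Published table of SSP clusters shared among lifestyles (CD-HIT at 70% identity,
# clusters with >= 3 species). Member abbreviations are resolved against the
# species registry via species_abbreviations.tsv; punctuation artifacts of the
# printed table were normalized, spelling variants are preserved and resolved
# by the abbreviation map. pfam "None" means no PFAM domain was assigned.
cluster_id	n_species	length_min	length_max	pfam	section	members	description
92	5	234	236	None	ecm_only	P. involutus; P. rubicondulus; P. microcarpus; P. tinctorius; S. citrinum	No PFAM domain
97	5	194	206	PF02845	ecm_only	P. involutus; P. rubicondulus; P. microcarpus; P. tinctorius; S. citrinum	CUE domain
52	3	110	257	PF01183	ecm_only	P. involutus; P. rubicondulus; Suillus luteus	Glycosyl hydrolases family 25
154	4	220	220	PF13460	ecm_only	P. involutus; P. rubicondulus; S. citrinum; S. luteus	NADH(P)-binding
169	4	132	189	PF10342	ecm_only	P. involutus; P. rubicondulus; P. microcarpus; P. tinctorius	Ser-Thr-rich gpi-anchored family
126	3	293	294	PF01764	ecm_only	P. microcarpus; P. tinctorius; S. citrinum	Lipase (class 3)
143	3	98	246	PF10342	ecm_only	P. involutus; P. rubicondulus; S. luteus	Ser-Thr-rich gpi-anchored family
147	3	160	234	PF04777	ecm_only	P. microcarpus; P. tinctorius; S. citrinum	Erv1 / Alr family
251	3	152	263	None	ecm_only	P. microcarpus; P. tinctorius; S. citrinum	No PFAM domain
264	3	241	252	None	ecm_only	P. microcarpus; P. tinctorius; S. citrinum	No PFAM domain
267	3	208	249	PF00491	ecm_only	P. involutus; P. rubicondulus; P. microcarpus	Arginase family
292	3	225	229	PF03227	ecm_only	P. microcarpus; P. tinctorius; S. citrinum	GILT/Thiol oxidoreductases
373	3	148	153	None	ecm_only	P. microcarpus; P. tinctorius; S. citrinum	No PFAM domain
381	3	141	145	PF07249	ecm_only	P. microcarpus; P. tinctorius; S. luteus	Cerato-platanin
385	3	144	144	PF07249	ecm_only	P. microcarpus; P. tinctorius; S. citrinum	Cerato-platanin
429	3	113	113	None	ecm_only	P. microcarpus; P. tinctorius; S. citrinum	No PFAM domain
473	3	55	77	None	ecm_only	P. involutus; P. microcarpus; S. citrinum	No PFAM domain
0	21	179	186	PF00025 PF00071	ecm_and_saprotroph	A. bisporus; A. muscara; A. thiersii; C. cinerea; G. trabeum; H. cylindrosporum; H. annosum; H. sublateritium; P. involutus; P. rubicondulus; P. croceum; P. microcarpus; P. tinctorius; P. ostreatus; P. crispa; P. strigozonata; S. commune; S. citrinum; S. lacrymans; S. luteus; T. versicolor	ADP-ribosylation family Ras family
1	18	217	240	PF00160	ecm_and_saprotroph	A. bisporus; A. muscara; A. thiersii; F. pinicola; G. trabeum; G. luxurians; H. annosum; H. sublateritium; L. bicolor; P. rubicondulus; P. chrysosporium; P. microcarpus; P. tinctorius; P. crispa; P. strigosozonata; S. citrinum; S. lacrymans; T. versicolor	Cyclophylin
12	10	224	247	PF01183	ecm_and_saprotroph	A. bisporus; A. subglabra; G. trabeum; P. rubicondulus; P. chrisosporium; P. ostreatus; P. strigosozonata; S. commune; S. lacrymans; T. versicolor	Glycosyl Hydrolase 25
25	8	67	73	PF08520	ecm_and_saprotroph	A. thiersii; F. pinicola; H. annosum; J. argillacea; L. bicolor; P. crispa; S. luteus; T. versicolor	Fungal protein of unknown function
50	5	254	257	PF00314	ecm_and_saprotroph	C. cinerea; F. mediterranea; H. cylindrosporum; H. sublateriutium; J. argillacea	Thaumatin family
16	7	238	257	PF03443	saprotroph_only	G. luxurians; H. annosum; J. argillacea; P. ostreatus; P. crispa; P. strigosozonata; T. versicolor	Glycosyl Hydrolase 61
56	5	242	248	PF03443	saprotroph_only	A. bisporus; A. thiersii; P. crispa; S. lacrymans; T. versicolor	Glycosyl Hydrolase 61
217	3	105	110	PF01185	saprotroph_only	F. mediterranea; G. luxurians; J. argillacea	Fungal hydrophobin
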