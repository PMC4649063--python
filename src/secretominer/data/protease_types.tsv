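# Default MEROPS family -> endo/exo mapping, following the figure legend that
# labels the plotted protease data (endo: A01 pepsin, M36 fungalysin,
# S53 sedolisin, S28 lysosomal Pro-Xaa carboxypeptidase; exo: S08 subtilisin,
# S09 carboxypeptidase, M28 aminopeptidase). The accompanying results text
# swaps S08/S09 and S28; the mapping is a plain data file so either variant
# is one edit away. Families outside this table are reported as unassigned.
family	type
A01	endo
M36	endo
S53	endo
S28	endo
S08	exo
S09	exo
M28	exo
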