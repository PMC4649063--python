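# Mapping from registry lifestyles onto the four comparison groups used for
# the SSP-cluster Venn partition. Lifestyles not listed here fall into
# "other" and do not define a Venn set of their own.
Ectomycorrhizal: ECM
White rot: white_rot
Brown rot: brown_rot
Litter decayers: litter_decayer
Pathogen: other
Orchid symbiont: other
Ericoid symbiont: other
Endophyte: other
Mycoparasitic: other
Yeast: other
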