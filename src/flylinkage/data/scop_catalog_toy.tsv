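gene_id	general_function	detailed_function	family
ALHF_04553.g3033	Metabolism	Redox	Cytochrome P450
ALHF_04445.g2939	Metabolism	Redox	Cytochrome P450
ALHF_03407.g2111	Metabolism	Other	Carboxylesterase
ALHF_10712.g5974	Regulation	Kinase/phosphatase	Protein tyrosine kinase
ALHF_06811.g4468	Regulation	Signal transduction	GPCR (rhodopsin family)
ALHF_01050.g580	Regulation	Signal transduction	Adenylate and Guanylate cyclase catalytic domain
ALHF_07511.g4836	Intra-cellular processes	Proteases	Peptidases
ALHF_05334.g3663	Intra-cellular processes	Proteases	Peptidases
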