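gene_id	ALHF	aabys	A2345	A1345	A1245	A1235	A1234
ALHF_04445.g2939	present	absent	present	present	present	present	absent
ALHF_04553.g3033	present	absent	present	present	present	present	absent
ALHF_10712.g5974	present	absent	present	present	present	present	absent
ALHF_03407.g2111	present	absent	present	absent	present	present	present
ALHF_01050.g580	present	absent	present	absent	present	present	present
ALHF_06811.g4468	present	absent	present	absent	present	present	present
ALHF_07511.g4836	present	absent	present	absent	present	present	present
ALHF_05334.g3663	present	absent	present	absent	present	present	present
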