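# tudecay built-in 3'UTR cis-element definitions (RNA alphabet, sense strand).
# PRE: Pumilio recognition element, the degenerate 8-mer UGUA(A/U/C)AUA.
# ARE: package-default AU-rich element core heptamer WAUUUAW (W = A/U); overridable.
# miR124_seed: package-default 7-mer site complementary to positions 2-8 of mature
#   miR-124 (miRBase dme-miR-124-3p, 5'-UAAGGCACGCGGUGAAUGCCA); overridable.
name	pattern	note
PRE	UGUA[AUC]AUA	Pumilio recognition element
ARE	WAUUUAW	AU-rich element core heptamer, package default
miR124_seed	GUGCCUU	miR-124 seed match (positions 2-8), package default
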