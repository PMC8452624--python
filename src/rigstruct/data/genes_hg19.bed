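chr4	54229097	54298245	PDGFRA
chr12	58141510	58149796	CDK4
chr9	21967751	21995300	CDKN2A
chrX	39909068	39956869	BCOR
chr17	29421945	29704695	NF1
chr17	7571720	7590868	TP53
chr7	116312444	116438440	MET
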