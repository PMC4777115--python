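chrom	pos	ref	alt	gene
chr5	41014230	G	T	GRAPL
chr5	41014231	C	T	GRAPL
chr5	41055619	G	C	FAM83G
chr6	24951743	G	T	PDILT
chr37	30832376	C	T	DLGAP2
chr12	14853811	C	T	TDRD6
chr20	39951727	G	T	USP4
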