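CHROM	POS	ALLELE	POP
1	100	G	POP1
1	600	T	POP1
1	600	G	POP2
1	1000	C	POP2
1	700	T	POP1
1	99999	A	POP1
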