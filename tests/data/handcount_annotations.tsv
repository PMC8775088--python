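chrom	pos	sift	polyphen2	mutation_assessor
1	700	D	D	H
1	800	D	D	H
1	900	D	D	L
1	1000	T	B	L
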