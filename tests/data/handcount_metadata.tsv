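sample	pop	super_pop	center
A	POP1	SUPER1	CTR1
B	POP1	SUPER1	CTR1
C	POP2	SUPER1	CTR2
D	POP2	SUPER1	CTR2
E	POP2	SUPER1
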