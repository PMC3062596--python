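protein_id	cog
pA1	J
pA2	C
pA3	R
pB1	J
pB1	L
pB2	E
pB3	T
pC1	K
pC2	G
pC3	S
pC4	D
pD1	L
pD2	P
pD3	O
pE1	J
pE2	N
pE3	K
pE4	C
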