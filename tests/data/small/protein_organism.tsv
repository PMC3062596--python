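protein_id	organism_id
pA1	orgA
pA2	orgA
pA3	orgA
pA4	orgA
pB1	orgB
pB2	orgB
pB3	orgB
pB4	orgB
pC1	orgC
pC2	orgC
pC3	orgC
pC4	orgC
pD1	orgD
pD2	orgD
pD3	orgD
pD4	orgD
pE1	orgE
pE2	orgE
pE3	orgE
pE4	orgE
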