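>pA1
ACDEFGHIKLMNPQRSTVWYACDEFGHIKLMNPQRSTVWYACDEFGHIKLMNPQRSTVWY
ACDEFGHIKLMNPQRSTVWYACDEFGHIKLMNPQRSTVWY
>pA2
ACDEFGHIKLMNPQRSTVWYACDEFGHIKLMNPQRSTVWYACDEFGHIKLMNPQRSTVWY
ACDEFGHIKLMNPQRSTVWYACDEFGHIKLMNPQRSTVWY
>pA3
ACDEFGHIKLMNPQRSTVWYACDEFGHIKLMNPQRSTVWYACDEFGHIKLMNPQRSTVWY
ACDEFGHIKLMNPQRSTVWYACDEFGHIKLMNPQRSTVWY
>pA4
ACDEFGHIKLMNPQRSTVWYACDEFGHIKLMNPQRSTVWYACDEFGHIKLMNPQRSTVWY
ACDEFGHIKLMNPQRSTVWYACDEFGHIKLMNPQRSTVWY
>pB1
ACDEFGHIKLMNPQRSTVWYACDEFGHIKLMNPQRSTVWYACDEFGHIKLMNPQRSTVWY
ACDEFGHIKLMNPQRSTVWYACDEFGHIKLMNPQRSTVWY
>pB2
ACDEFGHIKLMNPQRSTVWYACDEFGHIKLMNPQRSTVWYACDEFGHIKLMNPQRSTVWY
ACDEFGHIKLMNPQRSTVWYACDEFGHIKLMNPQRSTVWY
>pB3
ACDEFGHIKLMNPQRSTVWYACDEFGHIKLMNPQRSTVWYACDEFGHIKLMNPQRSTVWY
ACDEFGHIKLMNPQRSTVWYACDEFGHIKLMNPQRSTVWY
>pB4
ACDEFGHIKLMNPQRSTVWYACDEFGHIKLMNPQRSTVWYACDEFGHIKLMNPQRSTVWY
ACDEFGHIKLMNPQRSTVWYACDEFGHIKLMNPQRSTVWY
>pC1
ACDEFGHIKLMNPQRSTVWYACDEFGHIKLMNPQRSTVWYACDEFGHIKLMNPQRSTVWY
ACDEFGHIKLMNPQRSTVWYACDEFGHIKLMNPQRSTVWY
>pC2
ACDEFGHIKLMNPQRSTVWYACDEFGHIKLMNPQRSTVWYACDEFGHIKLMNPQRSTVWY
ACDEFGHIKLMNPQRSTVWYACDEFGHIKLMNPQRSTVWY
>pC3
ACDEFGHIKLMNPQRSTVWYACDEFGHIKLMNPQRSTVWYACDEFGHIKLMNPQRSTVWY
ACDEFGHIKLMNPQRSTVWYACDEFGHIKLMNPQRSTVWY
>pC4
ACDEFGHIKLMNPQRSTVWYACDEFGHIKLMNPQRSTVWYACDEFGHIKLMNPQRSTVWY
ACDEFGHIKLMNPQRSTVWYACDEFGHIKLMNPQRSTVWY
>pD1
ACDEFGHIKLMNPQRSTVWYACDEFGHIKLMNPQRSTVWYACDEFGHIKLMNPQRSTVWY
ACDEFGHIKLMNPQRSTVWYACDEFGHIKLMNPQRSTVWY
>pD2
ACDEFGHIKLMNPQRSTVWYACDEFGHIKLMNPQRSTVWYACDEFGHIKLMNPQRSTVWY
ACDEFGHIKLMNPQRSTVWYACDEFGHIKLMNPQRSTVWY
>pD3
ACDEFGHIKLMNPQRSTVWYACDEFGHIKLMNPQRSTVWYACDEFGHIKLMNPQRSTVWY
ACDEFGHIKLMNPQRSTVWYACDEFGHIKLMNPQRSTVWY
>pD4
ACDEFGHIKLMNPQRSTVWYACDEFGHIKLMNPQRSTVWYACDEFGHIKLMNPQRSTVWY
ACDEFGHIKLMNPQRSTVWYACDEFGHIKLMNPQRSTVWY
>pE1
ACDEFGHIKLMNPQRSTVWYACDEFGHIKLMNPQRSTVWYACDEFGHIKLMNPQRSTVWY
ACDEFGHIKLMNPQRSTVWYACDEFGHIKLMNPQRSTVWY
>pE2
ACDEFGHIKLMNPQRSTVWYACDEFGHIKLMNPQRSTVWYACDEFGHIKLMNPQRSTVWY
ACDEFGHIKLMNPQRSTVWYACDEFGHIKLMNPQRSTVWY
>pE3
ACDEFGHIKLMNPQRSTVWYACDEFGHIKLMNPQRSTVWYACDEFGHIKLMNPQRSTVWY
ACDEFGHIKLMNPQRSTVWYACDEFGHIKLMNPQRSTVWY
>pE4
ACDEFGHIKLMNPQRSTVWYACDEFGHIKLMNPQRSTVWYACDEFGHIKLMNPQRSTVWY
ACDEFGHIKLMNPQRSTVWYACDEFGHIKLMNPQRSTVWY
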