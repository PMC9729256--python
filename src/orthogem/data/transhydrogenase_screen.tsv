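genome	membrane_transhydrogenase	soluble_transhydrogenase
A. aceti TMW2.1153	yes	yes
A. ascendens LMG 1590	yes	no
A. ghanensis LMG 23848	yes	no
A. oryzifermentans SLV-7	yes	no
A. pasteurianus 386B	yes	no
A. pasteurianus Ab3	no	yes
A. persici TMW2.1084	yes	no
A. pomorum BDGP5	yes	no
A. senegalensis 108B	no	yes
A. sp. JWB	yes	no
A. tropicalis BDGP1	no	yes
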