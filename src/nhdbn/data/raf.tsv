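PKC	Raf
PKC	Mek
PKC	Jnk
PKC	P38
PKC	PKA
PKA	Raf
PKA	Mek
PKA	Erk
PKA	Akt
PKA	Jnk
PKA	P38
Raf	Mek
Mek	Erk
Erk	Akt
PIP3	PIP2
PIP3	Plcg
PIP3	Akt
Plcg	PIP2
Plcg	PKC
PIP2	PKC
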