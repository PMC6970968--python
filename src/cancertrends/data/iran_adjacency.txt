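# First-order neighbour pairs of Iranian provinces, by HASC code.
# One unordered edge per line; the graph is undirected.
AL TE
AL MN
AL QZ
AL MK
AR EA
AR GI
EA WA
EA ZA
WA KD
WA ZA
ZA KD
ZA HD
ZA QZ
ZA GI
GI QZ
GI MN
MN TE
MN SM
MN GO
MN QZ
GO SM
GO KS
KS KV
KS SM
KV SM
KV KJ
KJ SM
KJ YA
KJ KE
KJ SB
SM TE
SM QM
SM ES
TE QM
TE MK
QZ MK
QZ HD
QM ES
QM MK
MK ES
MK LO
MK HD
HD LO
HD BK
HD KD
KD BK
BK LO
BK IL
IL LO
IL KZ
LO ES
LO KZ
KZ ES
KZ CM
KZ KB
KZ BS
CM ES
CM KB
KB ES
KB FA
KB BS
BS FA
BS HG
FA ES
FA YA
FA KE
FA HG
ES YA
YA KE
KE HG
KE SB
HG SB
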