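Dab2
Esrrb
Fgfr2
Gata6
Kdelr3
Klf5
Lama1
Lrp2
Pdgfra
Sox17
Timd2
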