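Cdx2
Elf5
Eomes
Gata3
Id2
Klf5
Phlda2
Plac1
Tead4
Tfap2c
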