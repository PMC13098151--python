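Cdh1
Cldn6
Cldn7
Cripto
Epcam
Klf4
Nanog
Pou5f1
Sox2
Stat3
Tfcp2l1
Zfp42
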