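Actb
Eef1e1
Gapdh
H2az1
Hprt1
Pgk1
Ppia
Tbp
Tubb4b
Ubc
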