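element,bone_basic,marrow_basic,bone_alt,marrow_alt
H,0.035,0.105,0.012,0.116
C,0.16,0.414,0.0287,0.0
N,0.042,0.034,0.0,0.0
O,0.445,0.439,0.44,0.899
F,0.0,0.0,0.0096,0.0
Na,0.003,0.001,0.007,0.0
Mg,0.002,0.002,0.011,0.0
Si,0.0,0.0,0.000007,0.0
P,0.095,0.002,0.16,0.0
S,0.003,0.002,0.0,0.0
Cl,0.0,0.0,0.0074,0.0
K,0.0,0.0,0.0007,0.0
Ca,0.215,0.0,0.331,0.0
Fe,0.0,0.0,0.0000067,0.0
Zn,0.0,0.0,0.00017,0.0
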