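age,mineral_density,marrow_density
0-Y,1.65,1.0
1-Y,1.7,1.0
5-Y,1.8,1.0
10-Y,1.83,1.0
15-Y,1.85,1.0
adult,1.9,0.98
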