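group,tbth_cv,tbsp_cv,measured
pelvic,10,10,1
vertebrae,48,43,1
skull,8,15,1
other,22,23,0
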