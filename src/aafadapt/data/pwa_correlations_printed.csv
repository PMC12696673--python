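formant,paradigm,r,p
F1,gradual,-0.21,0.58
F1,sudden,-0.02,0.95
F2,gradual,-0.39,0.30
F2,sudden,-0.58,0.10
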