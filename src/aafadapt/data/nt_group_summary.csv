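formant,paradigm,measure,n,mean,sd
F1,sudden,adaptive,12,-23.66,35.02
F1,sudden,corrective,12,-9.85,17.22
F1,gradual,adaptive,12,-24.36,23.35
F1,gradual,corrective,12,-1.92,22.03
F2,sudden,adaptive,12,58.63,101.64
F2,sudden,corrective,12,5.43,28.25
F2,gradual,adaptive,12,49.07,119.18
F2,gradual,corrective,12,-2.16,29.38
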