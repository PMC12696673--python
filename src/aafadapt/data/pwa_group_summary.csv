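formant,paradigm,measure,n,mean,sd
F1,sudden,adaptive,9,-27.96,34.61
F1,sudden,corrective,9,1.23,22.33
F1,gradual,adaptive,9,-13.34,36.17
F1,gradual,corrective,9,-34.01,46.50
F2,sudden,adaptive,9,23.16,64.78
F2,sudden,corrective,9,25.08,47.80
F2,gradual,adaptive,9,48.90,101.55
F2,gradual,corrective,9,-11.72,54.80
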