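subject,formant,paradigm,adaptive,corrective
SS1,F1,sudden,-18.91,-11.10
SS2,F1,sudden,-33.32,-10.90
SS3,F1,sudden,-62.86,-21.95
SS4,F1,sudden,25.93,-5.26
SS5,F1,sudden,-87.73,-4.78
SS6,F1,sudden,-13.53,32.47
SS7,F1,sudden,-12.77,3.13
SS8,F1,sudden,-49.83,44.14
SS9,F1,sudden,1.36,-14.66
SS1,F1,gradual,7.76,-10.68
SS2,F1,gradual,-68.58,-20.68
SS3,F1,gradual,-2.29,-14.19
SS4,F1,gradual,-14.63,6.65
SS5,F1,gradual,-77.02,-35.00
SS6,F1,gradual,22.03,-145.74
SS7,F1,gradual,-4.26,-19.13
SS8,F1,gradual,24.33,-3.43
SS9,F1,gradual,-7.40,-63.88
SS1,F2,sudden,-30.79,19.18
SS2,F2,sudden,91.45,-14.72
SS3,F2,sudden,-45.64,64.84
SS4,F2,sudden,115.52,-14.31
SS5,F2,sudden,54.65,103.60
SS6,F2,sudden,73.27,-30.86
SS7,F2,sudden,-46.86,64.75
SS8,F2,sudden,37.84,-18.87
SS9,F2,sudden,-40.96,52.10
SS1,F2,gradual,-74.27,-18.69
SS2,F2,gradual,206.29,-67.71
SS3,F2,gradual,16.32,0.89
SS4,F2,gradual,83.29,-40.07
SS5,F2,gradual,199.19,13.29
SS6,F2,gradual,76.72,-109.58
SS7,F2,gradual,1.11,51.35
SS8,F2,gradual,-54.63,2.65
SS9,F2,gradual,-13.94,62.36
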