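subject,paradigm,measure,t,p
SS1,gradual,adaptive,1.32,0.107
SS2,gradual,adaptive,-1.82,0.048
SS3,gradual,adaptive,0.91,0.192
SS4,gradual,adaptive,0.40,0.348
SS5,gradual,adaptive,-2.17,0.027
SS6,gradual,adaptive,1.91,0.041
SS7,gradual,adaptive,0.83,0.213
SS8,gradual,adaptive,2.00,0.035
SS9,gradual,adaptive,0.70,0.250
SS1,gradual,corrective,-0.38,0.355
SS2,gradual,corrective,-0.82,0.215
SS3,gradual,corrective,-0.54,0.301
SS4,gradual,corrective,0.37,0.358
SS5,gradual,corrective,-1.44,0.088
SS6,gradual,corrective,-6.27,0.001
SS7,gradual,corrective,-0.75,0.234
SS8,gradual,corrective,-0.07,0.474
SS9,gradual,corrective,-2.70,0.010
SS1,sudden,adaptive,0.13,0.449
SS2,sudden,adaptive,-0.27,0.398
SS3,sudden,adaptive,-1.08,0.153
SS4,sudden,adaptive,1.36,0.101
SS5,sudden,adaptive,-1.76,0.053
SS6,sudden,adaptive,0.28,0.393
SS7,sudden,adaptive,0.30,0.385
SS8,sudden,adaptive,-0.72,0.244
SS9,sudden,adaptive,0.69,0.253
SS1,sudden,corrective,-0.07,0.473
SS2,sudden,corrective,-0.06,0.477
SS3,sudden,corrective,-0.68,0.257
SS4,sudden,corrective,0.26,0.401
SS5,sudden,corrective,0.28,0.391
SS6,sudden,corrective,2.36,0.019
SS7,sudden,corrective,0.72,0.242
SS8,sudden,corrective,3.01,0.006
SS9,sudden,corrective,-0.27,0.397
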