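category,count
adaptive only,3
corrective only,1
both,1
none,4
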