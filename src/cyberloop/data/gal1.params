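# GAL1 promoter model (fluorescence units, min).
vmax = 1.0
d = 0.01
lag = 15.0
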