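strategy,ly,qaly,cost
RCHOP,17.59,14.245,32520.82
I-RCHOP,20.13,15.479,74606.41
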