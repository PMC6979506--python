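0.90,0,0,0,0,0
0.004,0.96,0,0,0,0
0,0.012,0.97,0,0,0
0,0,0.017,0.98,0,0
0,0,0,0.012,0.96,0
0,0,0,0,0.018,0.99
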