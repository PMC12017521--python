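percent_stance,bw_fraction
0,0
15,0.05
50,0.3
80,1.0
100,0.2
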