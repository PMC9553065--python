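bin_low,bin_high,fraction
0,10,0.312500
10,20,0.270000
20,30,0.162500
30,40,0.090000
40,50,0.055000
50,60,0.037500
60,70,0.030000
70,80,0.022500
80,90,0.020000
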