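phi,r2,gamma11,gamma12,beta31,beta32,gamma21,gamma23
0.4,0.25,0.318,0.279,0.372,0.335,0.354,0.354
0.4,0.50,0.45,0.394,0.525,0.473,0.5,0.5
0.6,0.25,0.298,0.261,0.382,0.322,0.354,0.354
0.6,0.50,0.421,0.369,0.541,0.456,0.5,0.5
0.8,0.25,0.281,0.246,0.391,0.311,0.354,0.354
0.8,0.50,0.397,0.348,0.554,0.44,0.5,0.5
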