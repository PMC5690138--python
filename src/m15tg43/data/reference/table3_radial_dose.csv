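r_cm,g_L,unc
0.5,0.996,0.021
1,1.0,0.0
2,1.006,0.021
3,1.008,0.021
4,1.008,0.021
5,1.004,0.021
6,0.997,0.021
7,0.987,0.021
8,0.974,0.021
9,0.959,0.02
10,0.941,0.02
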