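r_cm,phi_an,unc
0.5,1.009,0.015
1.0,0.971,0.014
2.0,0.963,0.014
3.0,0.964,0.014
4.0,0.965,0.014
5.0,0.966,0.014
6.0,0.967,0.014
7.0,0.968,0.014
8.0,0.969,0.014
9.0,0.970,0.014
10.0,0.971,0.014
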