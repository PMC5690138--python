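energy_mev,mu_rho_cm2g,muen_rho_cm2g
0.01000,4.93092,4.742
0.01500,1.51786,1.334
0.02000,0.71798,0.5389
0.03000,0.32397,0.1537
0.04000,0.230673,0.06833
0.05000,0.196155,0.04098
0.06000,0.179075,0.03041
0.08000,0.161361,0.02407
0.10000,0.150936,0.02325
0.15000,0.134103,0.02496
0.20000,0.122511,0.02672
0.30000,0.106347,0.02872
0.40000,0.0952387,0.02949
0.50000,0.0869485,0.02966
0.60000,0.0804259,0.02953
0.80000,0.0706378,0.02882
1.00000,0.0634952,0.02789
1.25000,0.0567636,0.02666
1.50000,0.0515795,0.02547
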