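energy_mev,mu_rho_cm2g,muen_rho_cm2g
0.01000,5.15408,4.944
0.01500,1.57845,1.374
0.02000,0.749434,0.5503
0.03000,0.345037,0.1557
0.04000,0.249992,0.06947
0.05000,0.214782,0.04223
0.06000,0.197213,0.0319
0.08000,0.178635,0.02597
0.10000,0.167445,0.02546
0.15000,0.149005,0.02764
0.20000,0.136182,0.02967
0.30000,0.118241,0.03192
0.40000,0.105898,0.03279
0.50000,0.0966822,0.03299
0.60000,0.0894305,0.03284
0.80000,0.0785473,0.03206
1.00000,0.0706052,0.03103
1.25000,0.06312,0.02965
1.50000,0.0573554,0.02833
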