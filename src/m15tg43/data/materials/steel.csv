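energy_mev,mu_rho_cm2g,muen_rho_cm2g
0.01000,167.152,136.9
0.01500,55.0105,48.96
0.02000,24.4783,22.56
0.03000,7.59746,7.251
0.04000,3.16596,3.15013
0.05000,1.5902,1.58225
0.06000,0.913904,0.909334
0.08000,0.446531,0.4104
0.10000,0.281564,0.2177
0.15000,0.164031,0.07961
0.20000,0.130195,0.04825
0.30000,0.104047,0.03361
0.40000,0.09096,0.03039
0.50000,0.0822496,0.02914
0.60000,0.0757526,0.02836
0.80000,0.0662446,0.02714
1.00000,0.0594495,0.02603
1.25000,0.0530964,0.02472
1.50000,0.0482269,0.0236
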