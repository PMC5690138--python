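energy_mev,mu_rho_cm2g,muen_rho_cm2g
0.01000,80.1545,60.0029
0.01500,120.152,90.0042
0.02000,71.8491,53.7804
0.03000,24.3441,18.1575
0.04000,11.1396,8.25934
0.05000,6.01546,4.42093
0.06000,3.63163,2.63732
0.07610,1.80604,1.27421
0.07612,8.18604,6.05922
0.08000,7.16479,5.29462
0.10000,4.51887,3.3164
0.15000,1.61702,1.15193
0.20000,0.78806,0.538715
0.30000,0.305266,0.187992
0.40000,0.182396,0.103154
0.50000,0.129759,0.0688133
0.60000,0.102531,0.0522162
0.80000,0.0766818,0.0381636
1.00000,0.0634519,0.031796
1.25000,0.0552509,0.0287102
1.50000,0.0493911,0.0264755
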