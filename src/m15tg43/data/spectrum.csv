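energy_mev,intensity_per_decay,rel_unc
0.061486,1.199531e-02,1.667633e-02
0.063000,2.049198e-02,1.667633e-02
0.065122,2.628972e-02,1.250724e-02
0.066831,4.478248e-02,1.250724e-02
0.071413,7.097224e-03,2.501449e-02
0.073363,2.199140e-03,2.501449e-02
0.075749,1.529402e-02,2.501449e-02
0.077831,4.698162e-03,2.501449e-02
0.136343,1.829285e-03,3.335265e-02
0.201311,4.728151e-03,1.667633e-02
0.205794,3.338694e-02,1.250724e-02
0.283267,2.658960e-03,1.667633e-02
0.295956,2.869877e-01,4.169082e-03
0.308455,2.968839e-01,4.169082e-03
0.316506,8.282760e-01,3.335265e-03
0.374485,7.257161e-03,1.667633e-02
0.416469,6.697380e-03,1.667633e-02
0.420520,6.897302e-04,4.169082e-02
0.468069,4.782130e-01,3.335265e-03
0.484575,3.187753e-02,8.338163e-03
0.489060,4.378288e-03,1.667633e-02
0.588581,4.520232e-02,8.338163e-03
0.604411,8.226782e-02,6.670530e-03
0.612462,5.337912e-02,6.670530e-03
0.884537,2.908862e-03,1.667633e-02
1.061480,5.297928e-04,3.335265e-02
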