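form,parameter,value
poly5,a0,0.9919
poly5,a1,0.0092
poly5,a2,-0.0009
poly5,a3,-0.0001
poly5,a4,1.29e-05
poly5,a5,3.74e-07
double_exponential,C1,-0.08651
double_exponential,mu1,0.1312
double_exponential,C2,1.081
double_exponential,mu2,0.01549
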