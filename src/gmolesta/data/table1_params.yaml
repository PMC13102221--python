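# Published parameter estimates of the four-peak occurrence curve for
# G. molesta adults in Korean apple orchards (thermal time in DD above
# 8.1 degC, upper cutoff 32.2 degC, Jan-1 biofix).
alpha1: 0.2751
alpha2: 0.3501
alpha3: 0.1724
alpha4: 0.2024
beta1: 172.23
dbeta1: 464.08
dbeta2: 575.33
dbeta3: 604.38
gamma1: -7.6149
gamma2: 0.0586
gamma3: 0.0904
gamma4: 0.0604
parameterization: rate
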