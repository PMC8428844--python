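# Serial dilution, concave tradeoff, rich medium c(0) = 10 K
mode = "dilution"
seed = 0

[tradeoff]
gamma = 0.9

[environment]
supply = [1.0, 1.0, 1.0]
monod_k = 1.0
decay = 0.0
death_rate = 0.0

[dilution]
rho0 = 1e-3
c_init = 10.0
c_fin = 1e-8

[evolution]
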