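# Linear tradeoff, neutral evolution: gamma = 1, delta = 1
mode = "chemostat"
seed = 0

[tradeoff]
gamma = 1.0

[environment]
supply = [1.0, 1.0, 1.0]
monod_k = 1.0
decay = 0.1
death_rate = 1.0

[evolution]
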