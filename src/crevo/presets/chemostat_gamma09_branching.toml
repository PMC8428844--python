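# Concave tradeoff: gamma = 0.9, branching into three specialists
mode = "chemostat"
seed = 0

[tradeoff]
gamma = 0.9

[environment]
supply = [1.0, 1.0, 1.0]
monod_k = 1.0
decay = 0.1
death_rate = 0.25

[evolution]
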