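# Quasi-invariant Monte Carlo relaxation towards the beta steady state
[run]
T = 5.0
seed = 1

[dsmc]
n_particles = 100000
epsilon = 1e-3
bins = 100
segments = [[-0.6, 1.0, 0.625]]   # uniform with mean 0.2

[opinion.default]
lam = 1.0
sigma2 = 0.25
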