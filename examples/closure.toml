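# Coupled kinetic SEIR with fast opinion exchange (compare with `opikin macro`)
[run]
T = 100.0
dt = 0.1
n_nodes = 201
drift_mode = "linear"
snapshot_times = [100.0]

[epidemic]
beta = 0.4
alpha = 1.0
sigma_e = 0.5
gamma = 0.08333333333333333
tau = 1e-5

[opinion.default]
lam = 1.0
sigma2 = 1e-3

[init]
name = "split"   # S,E sceptical on [-1,0]; I,R aware on [0,1]
rho0 = { S = 0.97, E = 0.01, I = 0.01, R = 0.01 }
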