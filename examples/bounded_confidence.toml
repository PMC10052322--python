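# Bounded-confidence opinion clustering coupled to the epidemic
[run]
T = 100.0
dt = 0.1
n_nodes = 201
drift_mode = "nonlocal"
snapshot_times = [50.0, 100.0]

[epidemic]
beta = 0.4
alpha = 1.0
sigma_e = 0.5
gamma = 0.08333333333333333
tau = 1.0

[opinion.default]
lam = 1.0
sigma2 = 1e-3
kernel = { kind = "bounded_confidence", delta = 0.5 }

[init]
name = "mixed"   # S,E uniform on [-1,1]; I,R aware on [0,1]
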