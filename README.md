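# opikin

Kinetic models coupling **opinion formation about protective behaviour**
with **SEIR epidemic dynamics** — from binary agent interactions to
population-level ODEs.

During an outbreak, the effectiveness of non-pharmaceutical interventions
depends on how opinions about them spread: consensus, clustering or outright
polarization of beliefs feed back into the contact process that transmits
the disease.  `opikin` is a simulator for this interplay, aimed at
mathematical epidemiologists and kinetic-theory researchers.  Each agent
carries an opinion `w ∈ [-1, 1]` (`-1` = rejects protection, `+1` = maximal
protection) and an epidemiological state S/E/I/R; opinions evolve through
compromise-plus-noise binary exchanges, and transmission is damped by
protective opinions through the local incidence

    K(f_S, f_I)(w) = f_S(w) ∫ κ(w, w*) f_I(w*) dw*,
    κ(w, w*) = (β/4^α) (1-w)^α (1-w*)^α.

The package implements the full model hierarchy:

| scale | model | solver |
|---|---|---|
| microscopic | binary opinion exchanges, kernels P (constant, bounded-confidence, infection-driven, asymmetric) | `opikin.micro` |
| kinetic (particles) | Boltzmann-type opinion model, quasi-invariant regime | DSMC, Nanbu–Babovsky (`opikin.dsmc`) |
| kinetic (grid) | Fokker–Planck operator with no-flux boundaries; beta steady state `f∞ ∝ (1+w)^{(1+m)/ν-1}(1-w)^{(1-m)/ν-1}`, `ν = σ²/λ` | well-balanced Chang–Cooper finite volumes (`opikin.fokker_planck`, `opikin.equilibrium`) |
| coupled | kinetic SEIR with opinion-dependent incidence | Strang splitting: node-wise RK4 + structure-preserving grid step (`opikin.seir`) |
| macroscopic | mass/mean ODEs under the beta closure; saturated incidence with `R₀ = β(1-m̄_I)/(4γ)` | RK4 (`opikin.macro`) |

Opinion **polarization** (divergence of the density at an extreme opinion,
`ν > min(1±m)`) is the central phenomenon: depending on the initial bias of
the population it can either amplify or dampen the epidemic.

## Worked example

Fast opinion exchange (`τ = 10⁻⁵`): the kinetic system is expected to track
the beta-closure ODEs.  Susceptibles start sceptical (uniform on `[-1, 0]`,
mean −0.5), the 1% infected start aware (uniform on `[0, 1]`, mean +0.5):

```python
import numpy as np
from opikin import (EpidemicParams, OpinionGrid, OpinionParams,
                    build_initial_condition, initial_condition,
                    integrate_macro, macro_state, run_kinetic_seir, r0)
from opikin.macro import macro_trajectory_frame
from opikin.seir import COMPARTMENTS

grid = OpinionGrid(201)
init = build_initial_condition(initial_condition("split"), grid)
op = OpinionParams(lam=1.0, sigma2=1e-3)                 # nu_S = 1e-3
params = EpidemicParams(beta=0.4, alpha=1.0, sigma_e=0.5,
                        gamma=1/12, tau=1e-5)

obs, _ = run_kinetic_seir(init, params, op, T=100.0, dt=0.1)

y0 = macro_state([init.rho(J) for J in COMPARTMENTS],
                 [init.mean(J) for J in COMPARTMENTS])
times, Y = integrate_macro(y0, params, op.nu, 100.0, 0.1)
mac = macro_trajectory_frame(times, Y)

peak = obs["rho_I"].idxmax()
print(f"peak infected fraction: {obs['rho_I'].max():.4f} at t = {obs['t'][peak]:.1f}")
print(f"terminal recovered fraction: {obs['rho_R'].iloc[-1]:.4f}")
print(f"terminal susceptible mean opinion: {obs['m_S'].iloc[-1]:+.4f}")
sup = max(np.max(np.abs(obs[c].values - mac[c].values)) for c in mac.columns[1:])
print(f"sup-norm distance to the beta-closure ODE system: {sup:.2e}")
print(f"R0 at the pinned infected mean 0.5: {r0(0.4, 0.5, 1/12):.2f}")
```

prints

```
peak infected fraction: 0.2188 at t = 47.6
terminal recovered fraction: 0.8829
terminal susceptible mean opinion: -0.4994
sup-norm distance to the beta-closure ODE system: 2.09e-04
R0 at the pinned infected mean 0.5: 0.60
```

The epidemic peaks at ~22% infected and burns through 88% of this sceptical
population; the susceptible mean barely moves because `ν_S = 10⁻³` is deep
in the consensus regime (for `ν_S = 0` it is exactly frozen).  The kinetic
observables agree with the eight macroscopic ODEs to 2×10⁻⁴ — the closure
is valid because opinions relax much faster than the epidemic.  The last
line evaluates the basic reproduction number of the saturated-incidence
reduction: with infected agents pinned at mean opinion 0.5 the outbreak is
subcritical (`R₀ = 0.6 < 1`).

## Command line

Every solver is exposed as a subcommand writing CSV tables plus JSON
metadata (see `examples/*.toml` for annotated configurations):

```sh
opikin fp            --config examples/closure.toml --out results/
opikin dsmc          --config examples/dsmc.toml --out results/
opikin kinetic-seir  --config examples/closure.toml --out results/
opikin macro         --config examples/closure.toml --out results/
opikin sweep         --m0 0.5 --nu-max 10 --steps 11 --out results/
opikin run-experiment closure --scale desk --out results/
```

`opikin run-experiment` bundles the five reference studies:
`quasi-invariant` (DSMC vs beta law for ε ∈ {10⁻¹, 10⁻³}), `closure`
(kinetic vs macroscopic for τ ∈ {10⁻⁵, 1, 100}), `bounded-confidence`
(opinion clustering, Δ ∈ {1/2, 1/4}), `infection-driven` (epidemic-dependent
confidence threshold, C_I ∈ {0.01, 0.025, 0.05}) and `polarization`
(terminal recovered fraction across ν_S ∈ [0, 10]).

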