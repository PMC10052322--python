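# Methods

`opikin` simulates the coupled dynamics of opinions about protective
behaviour and the spread of an infectious disease, from the microscopic
(agent) scale to macroscopic (population) ODEs.  This note records the
models, the numerical choices, and what the bundled synthetic experiments do
and do not establish.

## The model hierarchy

**Microscopic scale.** Every agent carries an opinion `w` in `[-1, 1]`
(`-1` = rejection of protective behaviour, `+1` = maximal protection) and an
epidemiological state `J` in {S, E, I, R}.  Two agents of a compartment
update their opinions through a compromise-plus-self-thinking rule

    w'  = w  + lambda_J P(w, w*) (w* - w) + D(w) eta,
    w*' = w* + lambda_J P(w*, w) (w - w*) + D(w*) eta~,

with compromise propensity `lambda_J` in `[0, 1]`, an interaction kernel
`P in [0, 1]` (constant, bounded-confidence indicator, infection-driven
threshold switch, or linear asymmetric `p w* + q`), local diffusion
`D(w) = sqrt(1 - w^2)` vanishing at the extremes, and i.i.d. centred bounded
noises of variance `sigma_J^2`.  For symmetric kernels the pair mean is
conserved in expectation (exactly when `sigma^2 = 0`) and the pair energy is
dissipated by `-2 s(1-s)(w*-w)^2`, `s = lambda P`.

**Kinetic scale.** The compartment densities `f_J(w, t)` follow a
Boltzmann-type equation driven by these binary exchanges, coupled to SEIR
transitions.  Transmission is governed by the local incidence

    K(f_S, f_I)(w) = f_S(w) \int kappa(w, w*) f_I(w*) dw*,
    kappa(w, w*)   = (beta/4^alpha) (1-w)^alpha (1-w*)^alpha,

so contacts between sceptical agents transmit at the baseline rate while
protective agents are shielded; `alpha = 0` removes the feedback entirely
and recovers the classical SEIR model.  In the quasi-invariant regime
(`lambda -> eps lambda`, `sigma^2 -> eps sigma^2`, `eps -> 0`) the opinion
operator converges to a Fokker-Planck operator

    Qbar_J f = d_w [ lambda_J (w - m_J) f + (sigma_J^2/2) d_w((1-w^2) f) ]

(for `P == 1`; a nonlocal drift `lambda \int P(w,w*)(w-w*) f(w*) dw*` for
bounded-confidence kernels) with no-flux boundaries.  Its steady state for
the constant kernel is a beta law on `[-1, 1]` with conserved mean `m` and
shape ratio `nu = sigma^2/lambda`:

    f_inf(w) ~ (1+w)^{(1+m)/nu - 1} (1-w)^{(1-m)/nu - 1},
    <w> = m,   <w^2> = (nu + 2 m^2)/(2 + nu).

Consensus profiles arise for `nu < 1`; *opinion polarization* — divergence
of the density at an extreme — occurs when an exponent drops below zero,
i.e. `nu > min(1+m, 1-m)` (for `m != 0` this asymmetric convention is the
package's own; the symmetric case reduces to the usual `nu > 1`).

**Macroscopic scale.** Closing the moment hierarchy with the beta law
(valid for `alpha = 1` and fast opinion exchange, `tau << 1`) yields eight
ODEs for the mass fractions `rho_J` and mean opinions `m_J` (see
`opikin.macro`).  Pinning the infected mean at `m_bar_I` gives a
saturated-incidence model: `m_S` follows the logistic closed form
`m_S(t) = tanh(\int_0^t J(rho_I) ds - C_0/2)` and the effective transmission
`beta_bar (1 - m_S)` decays as awareness grows; its basic reproduction
number is `R_0 = beta (1 - m_bar_I) / (4 gamma)`.

## Numerical methods

**Particle solver (DSMC).** Nanbu-Babovsky pairing: a random permutation is
split into disjoint consecutive pairs, each interacting with probability
`dt/tau` (an odd leftover particle skips the step).  Quasi-invariant runs
measure time on the Fokker-Planck scale: parameters are scaled by `eps` and
the relaxation time to `eps*tau`, so with the default step `dt = eps` every
pair interacts each step and the run reaches Fokker-Planck time `T` in
`T/eps` steps.  This is the reading of "`dt = eps` over a fixed horizon"
under which the terminal ensemble converges to the beta law as `eps -> 0`;
simulating the unscaled Boltzmann clock instead would require `T/eps^2`
steps and leave the ensemble essentially at its initial state for small
`eps`.

**Noise and admissibility.** The noise law is uniform on `[-a, a]` with
`a = sqrt(3 sigma^2)` — the simplest centred, bounded, finite-variance
choice.  Admissibility (`|w'| <= 1`) is enforced by *symmetric support
truncation*: the draw is uniform on `[-a_max, a_max]` with
`a_max = min(a, (1 - |w_base|)/D(w))`, the direct implementation of the
model's own sufficient admissibility bound.  Because the truncated support
is symmetric, the noise stays exactly centred conditional on the current
opinion, so mean conservation survives at the boundary.  Alternatives were
measured and rejected: resampling the noise until admissible, or reflecting
at the boundary, both condition the noise on staying inside and bias it
inward — for a polarized population (`nu = 2`, mean 0.2) they drift the
ensemble mean to 0.09 and 0.14 respectively and visibly distort the
boundary layer, while truncation keeps the mean within Monte Carlo error.
The price is a locally reduced noise variance in an `O(a)` boundary layer,
which vanishes in the quasi-invariant limit.

**Grid solver.** Vertex-centred finite volumes on `n_w` equispaced nodes
(default 201, endpoints at exactly ±1), with half-width boundary cells so
that cell widths coincide with trapezoidal quadrature weights — the single
quadrature rule used for every mass, mean and L1 distance.  Fluxes use
Chang-Cooper-type exponential fitting with per-midpoint exponent
`lt = \int C/Dtilde dw`.  For the linear drift this integral has a closed
form (the log-ratio of the unnormalized beta law), making the scheme *well
balanced*: the nodal beta evaluation is an exact discrete steady state for
consensus profiles, and for polarized profiles — whose nodal values are
infinite at a boundary — the exponents are built instead from cell-averaged
equilibrium values (regularized incomplete beta), making the cell-averaged
beta law exactly stationary.  The split matters: a pure cell-average scheme
degrades the discrete mean of sharply peaked profiles (the closure-test
regime), while a pure nodal scheme collapses polarized mass onto the
boundary nodes.  For the nonlocal drift the exponent uses the midpoint rule;
the nonlocal integral itself is a cached kernel-matrix product.

Time stepping is semi-implicit by default: coefficients frozen at `t_n`, one
tridiagonal solve per step.  The system matrix is an M-matrix, so the step
is unconditionally positivity-preserving, and the flux form telescopes, so
the trapezoidal mass is conserved to round-off per step — essential in the
stiff regime `tau << dt`, where one step is in effect a projection onto the
local beta equilibrium.  A Crank-Nicolson variant (`scheme =
"crank-nicolson"`) averages the explicit and implicit fluxes; it is second
order on smooth states and is used for time-order verification, but it is
not unconditionally positive and is not the default.

**Coupled system.** Strang splitting `E_{dt/2} O_{dt} E_{dt/2}` between the
epidemic substep (node-wise classical RK4; the right-hand sides telescope,
so the total density is conserved node-wise) and the opinion substep (one
grid-solver step per compartment with the 1/tau scaling).  Lie splitting is
available for order comparisons; with the Crank-Nicolson substep, Strang
converges at second order globally and clearly outperforms Lie at equal
step size.  Because the opinion substep conserves compartment masses
exactly, the `alpha = 0` kinetic masses coincide with a classical SEIR RK4
trajectory on the half-step grid to round-off.

**Macroscopic ODEs.** Classical RK4 throughout (default `dt = 1e-2` for the
sweeps, `0.1` for the closure comparison).  Means of (almost) empty
compartments are guarded: when `rho_J < 1e-12` the corresponding mean
derivative is set to 0 (the flux-form limit), avoiding spurious blow-up in
sweeps seeded with tiny compartments; the kinetic observable tables carry
the previous mean forward in the same situation.  The saturated system
integrates the exposure `z' = 2 J(rho_I)` as an auxiliary variable so the
logistic mean is evaluated exactly at every stage; `tanh` form avoids
overflow for large exposures.

## Study designs (bundled experiments)

All initial conditions are piecewise-uniform by design; jumps placed on
grid nodes take the midpoint value, which makes the projected masses and
means exact (e.g. the split state has means exactly ∓0.5).

* **quasi-invariant** — pure opinion model, `P == 1`, `N = 1e5` particles
  (`1e6` at full scale), horizon 5, `eps in {1e-1, 1e-3}`, `nu in {0.25,
  2}`, initial means 0 and 0.2.  Terminal histograms (100 bins) are
  compared with *cell-averaged* beta values so that boundary-divergent
  polarized profiles are compared through integrable cell masses.  At
  `N = 1e5` the Monte Carlo floor of the L1 distance is ~0.02.
* **closure** — coupled kinetic SEIR (`beta = 0.4`, `sigma_E = 1/2`,
  `gamma = 1/12`, `alpha = 1`, `lambda = 1`, `sigma^2 = 1e-3`, 201 nodes,
  `dt = 0.1`, horizon 100) against the macroscopic ODEs for
  `tau in {1e-5, 1, 100}`.  Measured sup-norm discrepancy: ~2e-4 at
  `tau = 1e-5`, ~5e-2 at `tau = 100`.
* **bounded-confidence** — threshold 1/2 (and 1/4), broad susceptible
  opinions: the susceptible density forms two symmetric interior clusters
  and the sceptical cluster loses mass to infection.  Both this solver and
  an independent DSMC run place the clusters near ±0.40 at horizon 100; the
  clusters creep inward on much longer horizons (diffusive metastability,
  merging around t ~ 400), so cluster *positions* are reported but only the
  two-cluster structure is asserted.
* **infection-driven** — threshold switching from 0.1 to 0.5 when `rho_I`
  crosses `C_I in {0.01, 0.025, 0.05}`, initial infected mass `1e-3`,
  horizon 200: the epidemic peak and the terminal recovered fraction are
  both increasing in `C_I`.
* **polarization** — 11 values of `nu_S` in `[0, 10]` × two initial mean
  biases ±0.5, horizon 300, `dt = 1e-2`: the terminal recovered fraction is
  monotone increasing in `nu_S` for the protective bias and monotone
  decreasing for the sceptical one.

**What the synthetic experiments do not show.** All runs use stylized
piecewise-uniform initial opinions, a homogeneous population (no age or
contact structure, identical `lambda, sigma^2` across compartments), and
epidemic rates merely *plausible* for a respiratory disease; nothing is
calibrated to data, so passing tests establish internal consistency of the
model hierarchy and solvers, not predictive skill for any real epidemic.
Demographic stochasticity of the epidemic itself is not modelled (the
particle method randomizes opinions only).

## Known limitations

* The grid solver handles symmetric kernels only; the asymmetric linear
  kernel (Dirac concentration at an extreme) is available through the
  particle solver.
* The macroscopic closure is derived, and offered, for `alpha = 1` with the
  constant kernel; other kernels require the kinetic solver.
* Mean conservation on the grid is exact only up to quadrature: at 201
  nodes, ~1e-7 with a frozen drift mean, ~1e-5 (linear) to ~3e-5 (bounded
  confidence) over self-consistent transients.
* Convergence of the particle method to the beta law slows near the
  boundary for polarized `nu` (the equilibrium mass in the truncation layer
  scales like `a^{min(a_exp, b_exp)}`), which is why the polarized cases
  dominate the quasi-invariant error budget.
* The semi-implicit opinion substep is first order in time; the
  Crank-Nicolson option restores second order but should not be used in the
  stiff projection regime.
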