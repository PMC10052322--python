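"""Direct simulation Monte Carlo for the Boltzmann-type opinion model.

The binary-exchange Boltzmann dynamics is sampled with the Nanbu-Babovsky
variant: at each step the ensemble is randomly permuted into disjoint
consecutive pairs and each pair interacts with probability ``dt/tau``
(an odd leftover particle skips the step).  Admissibility of post-interaction
opinions is enforced by the symmetric support truncation of the noise
(see :func:`opikin.micro.interact_admissible`).

Quasi-invariant runs (:func:`run_quasi_invariant`) measure time on the
Fokker-Planck scale: the interaction parameters are scaled to
``(eps*lambda, eps*sigma^2)`` and the relaxation time to ``eps*tau``, so with
the default step ``dt = eps`` every pair interacts at each step and the
terminal ensemble approaches, as ``eps -> 0``, the beta steady state of the
limiting Fokker-Planck equation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .grid import CompartmentDensity, OpinionGrid
from .micro import NoiseModel, OpinionParams, interact_admissible


@dataclass(frozen=True)
class PiecewiseUniform:
    """Piecewise-constant probability density on [-1, 1].

    ``segments`` is a tuple of ``(lo, hi, height)`` pieces; their total mass
    must be 1 (checked to 1e-10).
    """

    segments: tuple

    def __post_init__(self):
        total = 0.0
        for lo, hi, h in self.segments:
            if lo < -1.0 - 1e-12 or hi > 1.0 + 1e-12 or hi <= lo or h < 0:
                raise ValueError(f"invalid segment ({lo}, {hi}, {h})")
            total += (hi - lo) * h
        if abs(total - 1.0) > 1e-10:
            raise ValueError(f"density must integrate to 1, got {total}")

    @property
    def mean(self) -> float:
        return sum(0.5 * (hi**2 - lo**2) * h for lo, hi, h in self.segments)

    @property
    def second_moment(self) -> float:
        return sum((hi**3 - lo**3) / 3.0 * h for lo, hi, h in self.segments)

    @property
    def std(self) -> float:
        return float(np.sqrt(self.second_moment - self.mean**2))

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        masses = np.array([(hi - lo) * h for lo, hi, h in self.segments])
        idx = rng.choice(len(self.segments), size=n, p=masses / masses.sum())
        lo = np.array([s[0] for s in self.segments])[idx]
        hi = np.array([s[1] for s in self.segments])[idx]
        return rng.uniform(lo, hi)


def uniform_spec() -> PiecewiseUniform:
    """Uniform opinions on [-1, 1] (mean 0)."""
    return PiecewiseUniform((( -1.0, 1.0, 0.5),))


def shifted_uniform_spec() -> PiecewiseUniform:
    """Uniform opinions on [-0.6, 1] with height 5/8 (mean 0.2)."""
    return PiecewiseUniform(((-0.6, 1.0, 0.625),))


@dataclass
class ParticleEnsemble:
    """Opinions of N particles at one time."""

    opinions: np.ndarray
    time: float = 0.0

    def __post_init__(self):
        self.opinions = np.asarray(self.opinions, dtype=float)
        if self.opinions.ndim != 1 or self.opinions.size < 1:
            raise ValueError("need a nonempty 1-d opinion array")
        if np.any(np.abs(self.opinions) > 1.0):
            raise ValueError("opinions must lie in [-1, 1]")

    @property
    def n(self) -> int:
        return self.opinions.size

    @property
    def mean(self) -> float:
        return float(self.opinions.mean())

    @property
    def variance(self) -> float:
        return float(self.opinions.var())


def init_ensemble(spec: PiecewiseUniform, n: int,
                  seed_or_rng: int | np.random.Generator = 0) -> ParticleEnsemble:
    """I.i.d. sample of ``n`` opinions from a piecewise-uniform density."""
    if n < 1:
        raise ValueError("need at least one particle")
    rng = np.random.default_rng(seed_or_rng) if not isinstance(
        seed_or_rng, np.random.Generator) else seed_or_rng
    return ParticleEnsemble(spec.sample(n, rng), time=0.0)


def nanbu_step(ensemble: ParticleEnsemble, dt: float, tau: float,
               params: OpinionParams, rng: np.random.Generator,
               rho_i: Optional[float] = None) -> ParticleEnsemble:
    """One Nanbu-Babovsky step: pair, interact with probability dt/tau."""
    if dt < 0 or tau <= 0:
        raise ValueError("need dt >= 0 and tau > 0")
    prob = dt / tau
    if prob > 1.0 + 1e-12:
        raise ValueError(f"dt/tau = {prob:.3g} > 1: interaction probability overflow")
    w = ensemble.opinions.copy()
    if dt == 0.0:
        return ParticleEnsemble(w, ensemble.time)
    n_pairs = w.size // 2
    perm = rng.permutation(w.size)
    first = perm[:n_pairs]
    second = perm[n_pairs:2 * n_pairs]
    if prob >= 1.0:
        act = np.ones(n_pairs, dtype=bool)
    else:
        act = rng.random(n_pairs) < prob
    ia, ib = first[act], second[act]
    if ia.size:
        noise = NoiseModel(params.sigma2)
        wa, wb = interact_admissible(w[ia], w[ib], params, noise, rng, rho_i)
        w[ia], w[ib] = wa, wb
    return ParticleEnsemble(w, ensemble.time + dt)


def run_quasi_invariant(spec: PiecewiseUniform, n: int, epsilon: float,
                        params: OpinionParams, T: float, tau: float = 1.0,
                        dt: Optional[float] = None, seed: int = 0,
                        snapshot_times: Optional[Sequence[float]] = None):
    """Quasi-invariant DSMC run on the Fokker-Planck time scale.

    Parameters are scaled to (eps*lambda, eps*sigma^2) and the relaxation
    time to eps*tau, so the horizon ``T`` is measured in Fokker-Planck time;
    the default step is ``dt = eps`` (per-pair interaction probability
    dt/(eps*tau) = 1/tau).  Returns ``(ensemble, snapshots)`` where
    ``snapshots`` is a list of ``ParticleEnsemble`` at the requested times
    (always including 0 and T).
    """
    if not 0.0 < epsilon <= 1.0:
        raise ValueError("epsilon must lie in (0, 1]")
    dt = epsilon if dt is None else dt
    rng = np.random.default_rng(seed)
    ens = init_ensemble(spec, n, rng)
    scaled = params.scaled(epsilon)
    tau_eff = epsilon * tau
    n_steps = int(np.ceil(T / dt - 1e-12))
    want = sorted(set(snapshot_times or [])) if snapshot_times else []
    snaps = [ParticleEnsemble(ens.opinions.copy(), 0.0)]
    next_want = 0
    for k in range(1, n_steps + 1):
        ens = nanbu_step(ens, dt, tau_eff, scaled, rng)
        while next_want < len(want) and want[next_want] <= k * dt + 1e-12:
            snaps.append(ParticleEnsemble(ens.opinions.copy(), ens.time))
            next_want += 1
    if abs(snaps[-1].time - ens.time) > 1e-12:
        snaps.append(ParticleEnsemble(ens.opinions.copy(), ens.time))
    return ens, snaps


def empirical_density(ensemble: ParticleEnsemble, grid: OpinionGrid) -> CompartmentDensity:
    """Histogram of the ensemble on the node-centred cells of ``grid``.

    The returned nodal values are counts / (N * cell width), so the
    trapezoidal integral over the grid is exactly 1.
    """
    if ensemble.n == 0:
        raise ValueError("empty ensemble")
    counts, _ = np.histogram(ensemble.opinions, bins=grid.cell_edges)
    return CompartmentDensity(grid, counts / (ensemble.n * grid.weights))


def histogram_density(ensemble: ParticleEnsemble, bins: int = 100):
    """Equal-width histogram on [-1, 1]; returns ``(edges, density)``."""
    counts, edges = np.histogram(ensemble.opinions, bins=bins, range=(-1.0, 1.0))
    width = 2.0 / bins
    return edges, counts / (ensemble.n * width)
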