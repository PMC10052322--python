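"""Beta-law steady state of the linear opinion Fokker-Planck operator.

With constant interaction kernel and local diffusion D(w) = sqrt(1 - w^2),
the stationary opinion density is a beta law on [-1, 1] parameterized by the
conserved mean ``m`` and the self-thinking/compromise ratio ``nu = sigma^2 /
lambda``::

    f_inf(w) = (1+w)^(a-1) (1-w)^(b-1) / (2^(a+b-1) B(a, b)),
    a = (1+m)/nu,  b = (1-m)/nu.

Consensus profiles (unimodal, interior) arise for small nu; opinion
polarization -- divergence of the density at an extreme opinion -- occurs
when one of the exponents drops below zero, i.e. nu > min(1+m, 1-m).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special

from .grid import OpinionGrid


@dataclass(frozen=True)
class BetaEquilibrium:
    """Stationary beta opinion distribution with mean ``m`` and ratio ``nu``."""

    m: float = 0.0
    nu: float = 1.0

    def __post_init__(self):
        if not -1.0 < self.m < 1.0:
            raise ValueError("the mean m must lie in (-1, 1)")
        if self.nu <= 0.0:
            raise ValueError("the ratio nu = sigma^2/lambda must be positive")

    # shape parameters of the underlying Beta((1+w)/2) law
    @property
    def a(self) -> float:
        return (1.0 + self.m) / self.nu

    @property
    def b(self) -> float:
        return (1.0 - self.m) / self.nu

    @property
    def mean(self) -> float:
        return self.m

    @property
    def second_moment(self) -> float:
        """Closed-form energy: nu/(2+nu) + 2 m^2/(2+nu)."""
        return (self.nu + 2.0 * self.m**2) / (2.0 + self.nu)

    @property
    def variance(self) -> float:
        return self.second_moment - self.m**2

    def density(self, w) -> np.ndarray:
        """Pointwise density; returns the (possibly infinite) limit at w = +-1."""
        w = np.asarray(w, dtype=float)
        if np.any(np.abs(w) > 1 + 1e-12):
            raise ValueError("opinions must lie in [-1, 1]")
        with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
            log_norm = ((2.0 / self.nu - 1.0) * np.log(2.0)
                        + special.betaln(self.a, self.b))
            # unit exponents contribute exactly 0, also at the endpoints
            t_lo = 0.0 if self.a == 1.0 else (self.a - 1.0) * np.log1p(w)
            t_hi = 0.0 if self.b == 1.0 else (self.b - 1.0) * np.log1p(-w)
            out = np.exp(t_lo + t_hi - log_norm)
        # resolve the 0 * inf ambiguities at the endpoints explicitly
        out = np.where(np.isnan(out), _endpoint_limit(w, self.a, self.b), out)
        return out if out.ndim else float(out)

    def log_unnormalized(self, w) -> np.ndarray:
        """log[(1+w)^(a-1) (1-w)^(b-1)]; -inf where a factor vanishes."""
        w = np.asarray(w, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            t_lo = 0.0 if self.a == 1.0 else (self.a - 1.0) * np.log1p(w)
            t_hi = 0.0 if self.b == 1.0 else (self.b - 1.0) * np.log1p(-w)
            return t_lo + t_hi

    def cell_masses(self, edges: np.ndarray) -> np.ndarray:
        """Exact probability mass between consecutive ``edges`` (incomplete beta)."""
        x = np.clip((np.asarray(edges, dtype=float) + 1.0) / 2.0, 0.0, 1.0)
        cdf = special.betainc(self.a, self.b, x)
        return np.diff(cdf)

    def cell_averages(self, grid: OpinionGrid) -> np.ndarray:
        """Cell-averaged density on the node-centred cells of ``grid``.

        Finite even when the pointwise density diverges at a boundary, and
        integrates exactly to 1 under the grid's trapezoidal weights.
        """
        masses = self.cell_masses(grid.cell_edges)
        return masses / grid.weights

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return 2.0 * rng.beta(self.a, self.b, size=n) - 1.0


def _endpoint_limit(w, a, b):
    """Limit of the density at w = +-1 (0 for exponent > 1, +inf for < 1)."""
    out = np.zeros_like(np.asarray(w, dtype=float))
    at_m1 = np.isclose(w, -1.0)
    at_p1 = np.isclose(w, 1.0)
    out = np.where(at_m1 & (a < 1.0), np.inf, out)
    out = np.where(at_p1 & (b < 1.0), np.inf, out)
    return out


def beta_density(eq: BetaEquilibrium, w):
    """Density of the beta steady state at opinion(s) ``w``."""
    return eq.density(w)


def is_polarized(eq: BetaEquilibrium) -> bool:
    """Whether the steady state diverges at an extreme opinion.

    Convention: polarization iff ``nu > min(1+m, 1-m)`` (an exponent of the
    beta law is below zero, so the density blows up at that boundary).  At
    equality the profile is uniform-like at the boundary, not divergent.
    """
    return eq.nu > min(1.0 + eq.m, 1.0 - eq.m)
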