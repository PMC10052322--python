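"""Microscopic binary opinion exchanges.

Two agents in compartment J with opinions ``(w, w*)`` update through a
compromise-plus-self-thinking rule::

    w'  = w  + lambda_J P(w, w*) (w* - w) + D(w)  eta
    w*' = w* + lambda_J P(w*, w) (w - w*) + D(w*) eta~

where ``P`` is an interaction kernel with values in [0, 1], ``D(w) =
sqrt(1 - w^2)`` is the local diffusion (vanishing at the extreme opinions)
and ``eta, eta~`` are i.i.d. centred bounded noises with variance
``sigma_J^2``.  For symmetric kernels the pair mean is conserved in
expectation (exactly for zero noise) and the pair energy is dissipated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

KERNEL_KINDS = ("constant", "bounded_confidence", "infection_driven", "linear_asymmetric")


@dataclass(frozen=True)
class InteractionKernel:
    """Interaction function P(w, w*) in [0, 1].

    kind
        ``constant``            P == 1.
        ``bounded_confidence``  indicator of |w - w*| <= delta (closed inequality).
        ``infection_driven``    bounded confidence with threshold delta1 while the
                                infected fraction rho_I stays below c_i, delta2 above.
        ``linear_asymmetric``   P(w, w*) = p*w* + q (mean no longer conserved).
    """

    kind: str = "constant"
    delta: float = 2.0
    delta1: float = 0.1
    delta2: float = 0.5
    c_i: float = 0.01
    p: float = 0.0
    q: float = 1.0

    def __post_init__(self):
        if self.kind not in KERNEL_KINDS:
            raise ValueError(f"unknown kernel kind {self.kind!r}")
        if self.kind == "bounded_confidence" and not 0.0 <= self.delta <= 2.0:
            raise ValueError("confidence threshold delta must lie in [0, 2]")
        if self.kind == "infection_driven":
            if not (0.0 <= self.delta1 < self.delta2 <= 2.0):
                raise ValueError("infection-driven kernel needs 0 <= delta1 < delta2 <= 2")
            if not 0.0 < self.c_i < 1.0:
                raise ValueError("infection-driven switch level c_i must lie in (0, 1)")
        if self.kind == "linear_asymmetric":
            if not 0.0 <= self.q <= 1.0:
                raise ValueError("asymmetric kernel needs q in [0, 1]")
            if abs(self.p) > min(self.q, 1.0 - self.q) + 1e-15:
                raise ValueError("asymmetric kernel needs |p| <= min(q, 1-q)")

    @property
    def symmetric(self) -> bool:
        return self.kind in ("constant", "bounded_confidence", "infection_driven")

    def __call__(self, w, w_star, rho_i: Optional[float] = None):
        return evaluate_P(self, w, w_star, rho_i)


def evaluate_P(kernel: InteractionKernel, w, w_star, rho_i: Optional[float] = None):
    """Evaluate the interaction kernel; broadcasts over array arguments."""
    w = np.asarray(w, dtype=float)
    w_star = np.asarray(w_star, dtype=float)
    if np.any(np.abs(w) > 1 + 1e-12) or np.any(np.abs(w_star) > 1 + 1e-12):
        raise ValueError("opinions must lie in [-1, 1]")
    if kernel.kind == "constant":
        return np.broadcast_arrays(np.ones_like(w), np.ones_like(w_star))[0] * 1.0
    if kernel.kind == "bounded_confidence":
        return (np.abs(w - w_star) <= kernel.delta).astype(float)
    if kernel.kind == "infection_driven":
        if rho_i is None:
            raise ValueError("infection-driven kernel requires the infected fraction rho_i")
        delta = kernel.delta1 if rho_i <= kernel.c_i else kernel.delta2
        return (np.abs(w - w_star) <= delta).astype(float)
    # linear_asymmetric: P depends on the partner opinion only
    return kernel.p * w_star + kernel.q


def local_diffusion(w):
    """Local diffusion D(w) = sqrt(1 - w^2); vanishes at w = +-1."""
    w = np.asarray(w, dtype=float)
    if np.any(np.abs(w) > 1 + 1e-12):
        raise ValueError("opinions must lie in [-1, 1]")
    return np.sqrt(np.clip(1.0 - w * w, 0.0, None))


@dataclass(frozen=True)
class OpinionParams:
    """Compromise propensity, self-thinking variance and kernel of one compartment."""

    lam: float = 1.0
    sigma2: float = 0.0
    kernel: InteractionKernel = field(default_factory=InteractionKernel)

    def __post_init__(self):
        # lam = 0 (no compromise) is admitted as the degenerate zero-flux case
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError("compromise propensity lam must lie in [0, 1]")
        if self.sigma2 < 0.0:
            raise ValueError("noise variance sigma2 must be >= 0")

    @property
    def nu(self) -> float:
        """Self-thinking to compromise ratio nu = sigma^2 / lambda."""
        if self.lam == 0.0:
            raise ValueError("nu undefined for lam = 0")
        return self.sigma2 / self.lam

    def scaled(self, epsilon: float) -> "OpinionParams":
        """Quasi-invariant rescaling lambda -> eps*lambda, sigma^2 -> eps*sigma^2."""
        return OpinionParams(self.lam * epsilon, self.sigma2 * epsilon, self.kernel)


@dataclass(frozen=True)
class NoiseModel:
    """Centred bounded noise; uniform on [-a, a] with a = sqrt(3 sigma^2).

    The uniform law is the simplest one satisfying the centring, finite
    variance and bounded-support requirements of the binary rule.  If
    ``support_bound`` (= c(1 - lambda_J)) is given, the half-width must not
    exceed it, otherwise admissibility cannot be guaranteed a priori and an
    error is raised; the particle solvers instead leave it unset and enforce
    admissibility by rejection resampling.
    """

    variance: float
    support_bound: Optional[float] = None

    def __post_init__(self):
        if self.variance < 0.0:
            raise ValueError("noise variance must be >= 0")
        if self.support_bound is not None and self.half_width > self.support_bound + 1e-15:
            raise ValueError(
                "requested variance incompatible with the support bound: "
                f"sqrt(3 sigma^2) = {self.half_width:.3g} > {self.support_bound:.3g}"
            )

    @property
    def half_width(self) -> float:
        return math.sqrt(3.0 * self.variance)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if n < 1:
            raise ValueError("need at least one draw")
        if self.variance == 0.0:
            return np.zeros(n)
        return rng.uniform(-self.half_width, self.half_width, size=n)


def sample_noise(model: NoiseModel, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` i.i.d. noise values from ``model`` (see :class:`NoiseModel`)."""
    return model.sample(n, rng)


def binary_interact(w, w_star, params: OpinionParams, eta, eta_tilde,
                    rho_i: Optional[float] = None):
    """Raw binary update; broadcasts over arrays.

    Applies the compromise-plus-noise rule with the given noise draws; no
    admissibility enforcement (use :func:`interact_admissible` for that).
    With zero noise the outputs are convex combinations of the inputs and
    therefore always admissible.
    """
    w = np.asarray(w, dtype=float)
    w_star = np.asarray(w_star, dtype=float)
    p_fwd = evaluate_P(params.kernel, w, w_star, rho_i)
    p_bwd = evaluate_P(params.kernel, w_star, w, rho_i)
    w_new = w + params.lam * p_fwd * (w_star - w) + local_diffusion(w) * np.asarray(eta)
    w_star_new = (w_star + params.lam * p_bwd * (w - w_star)
                  + local_diffusion(w_star) * np.asarray(eta_tilde))
    return w_new, w_star_new


def interact_admissible(w, w_star, params: OpinionParams, noise: NoiseModel,
                        rng: np.random.Generator, rho_i: Optional[float] = None):
    """Vectorized admissible binary update (symmetric support truncation).

    The admissibility condition of the binary rule bounds the noise through
    ``D(w)|eta| <= (1 - lambda P)(1 - |w|)``, i.e. the noise support shrinks
    as an opinion approaches an extreme.  The draw is therefore taken
    uniformly on the *symmetric* interval ``[-a_max, a_max]`` with ``a_max =
    min(a, (1 - |w_base|)/D(w))``, where ``w_base`` is the post-compromise
    opinion.  The conditional noise stays exactly centred, so the pair mean
    is conserved in expectation everywhere (including the boundary layer),
    and every output lies in [-1, 1] by construction.  Returns ``(w', w*')``.
    """
    w = np.atleast_1d(np.asarray(w, dtype=float))
    w_star = np.atleast_1d(np.asarray(w_star, dtype=float))
    p_fwd = evaluate_P(params.kernel, w, w_star, rho_i)
    p_bwd = evaluate_P(params.kernel, w_star, w, rho_i)
    base_fwd = w + params.lam * p_fwd * (w_star - w)
    base_bwd = w_star + params.lam * p_bwd * (w - w_star)
    if noise.variance == 0.0:
        return base_fwd, base_bwd

    def _with_noise(base, diff):
        with np.errstate(divide="ignore"):
            a_max = np.minimum(noise.half_width,
                               (1.0 - np.abs(base)) / np.where(diff > 0, diff, np.inf))
        return base + diff * a_max * rng.uniform(-1.0, 1.0, size=base.size)

    return (_with_noise(base_fwd, local_diffusion(w)),
            _with_noise(base_bwd, local_diffusion(w_star)))


def energy_change(w: float, w_star: float, lambda_j: float, p_value: float) -> float:
    """Exact pair-energy change for a noiseless symmetric interaction.

    ``(w')^2 + (w*')^2 - w^2 - w*^2 = -2 s (1 - s) (w* - w)^2`` with
    ``s = lambda_J * P``; nonpositive for s in [0, 1].
    """
    s = lambda_j * p_value
    return -2.0 * s * (1.0 - s) * (w_star - w) ** 2
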