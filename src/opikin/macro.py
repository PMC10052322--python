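"""Macroscopic SEIR dynamics with opinion closure.

Integrating the kinetic system over the opinion variable and closing the
moment hierarchy with the beta steady state (valid for the constant kernel,
alpha = 1 incidence and fast opinion exchange, tau << 1) yields an ODE
system for the mass fractions rho_J and mean opinions m_J::

    rho_S' = -(beta/4)(1-m_I)(1-m_S) rho_S rho_I,
    rho_E' = +(beta/4)(1-m_I)(1-m_S) rho_S rho_I - sigma_E rho_E,
    rho_I' = sigma_E rho_E - gamma rho_I,
    rho_R' = gamma rho_I,
    m_S'   = (beta/4)(nu_S/(2+nu_S))(1-m_I) rho_I (1 - m_S^2),
    m_E'   = (beta/4)(rho_S rho_I/rho_E)(1-m_I)
             [m_S - (nu_S + 2 m_S^2)/(2+nu_S) - m_E (1-m_S)],
    m_I'   = sigma_E (rho_E/rho_I)(m_E - m_I),
    m_R'   = gamma (rho_I/rho_R)(m_I - m_R).

For nu_S = 0 (susceptible consensus) m_S is constant.  Pinning the infected
mean to a constant value gives the saturated-incidence reduction, whose
susceptible mean follows a logistic closed form and whose basic reproduction
number is R_0 = beta (1 - m_I) / (4 gamma).

All integrators are classical RK4 and accept vectorized states (trailing
axes broadcast), which the polarization sweep exploits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .seir import EpidemicParams

GUARD = 1e-12  # below this mass a compartment's mean derivative is frozen at 0

STATE_ORDER = ("rho_S", "rho_E", "rho_I", "rho_R", "m_S", "m_E", "m_I", "m_R")


def closure_m2(rho_j: float, m_j: float, nu_j: float):
    """Beta-closure second moment rho_J (nu_J + 2 m_J^2) / (2 + nu_J)."""
    return rho_j * (nu_j + 2.0 * np.asarray(m_j) ** 2) / (2.0 + nu_j)


def macro_state(rho: Sequence[float], m: Sequence[float]) -> np.ndarray:
    """Pack (rho_S..rho_R, m_S..m_R) into the 8-component state vector."""
    y = np.concatenate([np.asarray(rho, float), np.asarray(m, float)])
    if abs(y[:4].sum() - 1.0) > 1e-8:
        raise ValueError("mass fractions must sum to 1")
    if np.any(np.abs(y[4:]) > 1.0 + 1e-12):
        raise ValueError("mean opinions must lie in [-1, 1]")
    return y


def macro_rhs(y: np.ndarray, params: EpidemicParams, nu_s: float) -> np.ndarray:
    """Time derivative of the 8-component macroscopic state.

    ``y`` may carry trailing axes (vectorized states); ``nu_s`` may then be
    an array broadcastable against them.  Divisions by (almost) empty
    compartments are guarded: the corresponding mean derivative is 0.
    """
    y = np.asarray(y, dtype=float)
    rS, rE, rI, rR = y[0], y[1], y[2], y[3]
    mS, mE, mI, mR = y[4], y[5], y[6], y[7]
    beta4 = params.beta / 4.0
    nu_s = np.asarray(nu_s, dtype=float)

    infection = beta4 * (1.0 - mI) * (1.0 - mS) * rS * rI
    d = np.empty_like(y)
    d[0] = -infection
    d[1] = infection - params.sigma_e * rE
    d[2] = params.sigma_e * rE - params.gamma * rI
    d[3] = params.gamma * rI

    e2 = (nu_s + 2.0 * mS**2) / (2.0 + nu_s)  # closure second moment of S (per unit mass)
    d[4] = beta4 * nu_s / (2.0 + nu_s) * (1.0 - mI) * rI * (1.0 - mS**2)
    with np.errstate(divide="ignore", invalid="ignore"):
        dmE = beta4 * rS * rI / rE * (1.0 - mI) * (mS - e2 - mE * (1.0 - mS))
        dmI = params.sigma_e * rE / rI * (mE - mI)
        dmR = params.gamma * rI / rR * (mI - mR)
    d[5] = np.where(rE < GUARD, 0.0, dmE)
    d[6] = np.where(rI < GUARD, 0.0, dmI)
    d[7] = np.where(rR < GUARD, 0.0, dmR)
    return d


def _rk4(rhs: Callable[[float, np.ndarray], np.ndarray], y0: np.ndarray,
         T: float, dt: float, record_every: int = 1):
    """Classical RK4 with fixed step; returns (times, states-stacked)."""
    n_steps = int(round(T / dt))
    y = np.array(y0, dtype=float)
    times = [0.0]
    out = [y.copy()]
    t = 0.0
    for k in range(1, n_steps + 1):
        k1 = rhs(t, y)
        k2 = rhs(t + 0.5 * dt, y + 0.5 * dt * k1)
        k3 = rhs(t + 0.5 * dt, y + 0.5 * dt * k2)
        k4 = rhs(t + dt, y + dt * k3)
        y = y + dt / 6.0 * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        t = k * dt
        if k % record_every == 0 or k == n_steps:
            times.append(t)
            out.append(y.copy())
    return np.array(times), np.stack(out)


def integrate_macro(y0: np.ndarray, params: EpidemicParams, nu_s,
                    T: float, dt: float, record_every: int = 1,
                    pinned_m_i: float | None = None):
    """RK4 trajectory of the macroscopic system.

    ``pinned_m_i`` freezes the infected mean at a constant value (saturated-
    incidence regime).  Returns ``(times, Y)`` with ``Y[k]`` the state at
    ``times[k]`` (trailing axes preserved for vectorized runs).
    """

    def rhs(t, y):
        if pinned_m_i is not None:
            y = y.copy()
            y[6] = pinned_m_i
        d = macro_rhs(y, params, nu_s)
        if pinned_m_i is not None:
            d[6] = 0.0
        return d

    y0 = np.array(y0, dtype=float)
    if pinned_m_i is not None:
        y0[6] = pinned_m_i
    times, Y = _rk4(rhs, y0, T, dt, record_every)
    # clip round-off excursions of the means outside [-1, 1]
    Y[:, 4:8] = np.clip(Y[:, 4:8], -1.0, 1.0)
    return times, Y


def macro_trajectory_frame(times: np.ndarray, Y: np.ndarray) -> pd.DataFrame:
    """DataFrame view of a scalar (non-vectorized) macroscopic trajectory."""
    return pd.DataFrame(Y, columns=list(STATE_ORDER)).assign(t=times)[
        ["t", *STATE_ORDER]]


def classical_seir(rho0: Sequence[float], params: EpidemicParams,
                   T: float, dt: float, record_every: int = 1):
    """Classical SEIR reference (opinion-independent incidence kappa == beta)."""
    rho0 = np.asarray(rho0, dtype=float)

    def rhs(t, r):
        inc = params.beta * r[0] * r[2]
        return np.array([-inc, inc - params.sigma_e * r[1],
                         params.sigma_e * r[1] - params.gamma * r[2],
                         params.gamma * r[2]])

    return _rk4(rhs, rho0, T, dt, record_every)


# ----------------------------------------------------------------------
# saturated incidence reduction (pinned infected mean)
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class SaturatedParams:
    """Parameters of the saturated-incidence reduction.

    ``m_bar_i`` is the pinned infected mean in (0, 1); ``m_s0`` the initial
    susceptible mean; ``nu_s`` the susceptible polarization ratio.
    """

    beta: float
    sigma_e: float
    gamma: float
    m_bar_i: float
    m_s0: float
    nu_s: float

    def __post_init__(self):
        if not 0.0 < self.m_bar_i < 1.0:
            raise ValueError("m_bar_i must lie in (0, 1)")
        if not -1.0 <= self.m_s0 <= 1.0:
            raise ValueError("m_s0 must lie in [-1, 1]")
        if self.nu_s < 0.0:
            raise ValueError("nu_s must be >= 0")

    @property
    def beta_bar(self) -> float:
        return self.beta / 4.0 * (1.0 - self.m_bar_i)

    @property
    def c0(self) -> float:
        if abs(self.m_s0) >= 1.0:
            raise ValueError("C0 is finite only for |m_s0| < 1")
        return math.log((1.0 - self.m_s0) / (1.0 + self.m_s0))

    def j_rate(self, rho_i):
        """J(rho_I) = (beta/4)(nu_S/(2+nu_S))(1 - m_bar_I) rho_I."""
        return (self.beta / 4.0 * self.nu_s / (2.0 + self.nu_s)
                * (1.0 - self.m_bar_i) * np.asarray(rho_i))

    def epidemic_params(self) -> EpidemicParams:
        return EpidemicParams(beta=self.beta, alpha=1.0, sigma_e=self.sigma_e,
                              gamma=self.gamma)


def saturated_mS(t, params: SaturatedParams, rho_i_path):
    """Logistic closed form of the susceptible mean under a pinned m_I.

    ``rho_i_path`` is either a callable rho_I(s) or a pair of arrays
    ``(s, rho_I)`` sampled on a grid; the exposure integral int_0^t J ds is
    accumulated by the trapezoidal rule on a fine grid.  ``t`` may be an
    array.  For m_s0 = +-1 the constant branch is returned.
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    if abs(params.m_s0) >= 1.0:
        out = np.full_like(t, params.m_s0)
        return out if out.size > 1 else float(out[0])
    if callable(rho_i_path):
        s = np.linspace(0.0, float(t.max()), max(2, int(1000 * max(t.max(), 1e-9)) + 1))
        rho = np.asarray(rho_i_path(s), dtype=float)
    else:
        s, rho = (np.asarray(a, dtype=float) for a in rho_i_path)
    J = params.j_rate(rho)
    cumulative = np.concatenate(([0.0], np.cumsum(0.5 * (J[1:] + J[:-1]) * np.diff(s))))
    integral = np.interp(t, s, cumulative)
    # (e^z - e^c0)/(e^c0 + e^z) = tanh((z - c0)/2), overflow-safe
    out = np.tanh(integral - 0.5 * params.c0)
    return out if out.size > 1 else float(out[0])


def saturated_system(rho0: Sequence[float], params: SaturatedParams,
                     T: float, dt: float, record_every: int = 1):
    """Mass fractions under the saturated incidence rate.

    The exposure integral is carried as an auxiliary ODE variable
    ``z' = 2 J(rho_I)`` so the closed-form mean ``m_S = (e^z - e^{C0}) /
    (e^{C0} + e^z)`` is evaluated exactly at every RK4 stage.  Returns a
    DataFrame with the masses, m_S and the saturation factor H = 1 - m_S.
    """
    rho0 = np.asarray(rho0, dtype=float)
    frozen = abs(params.m_s0) >= 1.0
    c0 = None if frozen else params.c0
    bbar = params.beta_bar

    def m_s_of_z(z):
        return params.m_s0 if frozen else math.tanh(0.5 * (z - c0))

    def rhs(t, y):
        rS, rE, rI, rR, z = y
        m_s = m_s_of_z(z)
        inc = bbar * (1.0 - m_s) * rS * rI
        return np.array([-inc, inc - params.sigma_e * rE,
                         params.sigma_e * rE - params.gamma * rI,
                         params.gamma * rI, 2.0 * params.j_rate(rI)])

    times, Y = _rk4(rhs, np.concatenate([rho0, [0.0]]), T, dt, record_every)
    m_s = np.array([m_s_of_z(z) for z in Y[:, 4]])
    frame = pd.DataFrame(Y[:, :4], columns=["rho_S", "rho_E", "rho_I", "rho_R"])
    frame.insert(0, "t", times)
    frame["m_S"] = m_s
    frame["H"] = 1.0 - m_s
    return frame


def r0(beta: float, m_bar_i: float, gamma: float) -> float:
    """Basic reproduction number beta (1 - m_bar_I) / (4 gamma)."""
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    return beta * (1.0 - m_bar_i) / (4.0 * gamma)


def polarization_sweep(nu_grid: Sequence[float], m0: float,
                       params: EpidemicParams, T: float = 300.0,
                       dt: float = 1e-2,
                       rho0: Sequence[float] = (0.97, 0.01, 0.01, 0.01)
                       ) -> pd.DataFrame:
    """Terminal recovered fraction across susceptible polarization levels.

    All compartments start with the common mean opinion ``m0``; each value of
    ``nu_S`` is integrated (vectorized) to time ``T`` and the terminal
    ``rho_R`` recorded.
    """
    nu = np.asarray(nu_grid, dtype=float)
    if np.any(nu < 0) or np.any(nu > 10.0 + 1e-12):
        raise ValueError("nu_S values must lie in [0, 10]")
    y0 = np.empty((8, nu.size))
    y0[:4] = np.asarray(rho0, dtype=float)[:, None]
    y0[4:] = m0
    _, Y = integrate_macro(y0, params, nu, T, dt, record_every=max(1, int(round(T / dt))))
    return pd.DataFrame({"nu_S": nu, "rho_R_T": Y[-1, 3, :]})
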