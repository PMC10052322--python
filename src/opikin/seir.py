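"""Coupled kinetic SEIR dynamics with opinion-dependent incidence.

Each compartment J in {S, E, I, R} carries an opinion density f_J(w, t) on
[-1, 1].  Transmission is governed by the local incidence operator::

    K(f_S, f_I)(w) = f_S(w) \int kappa(w, w*) f_I(w*) dw*,
    kappa(w, w*) = (beta / 4^alpha) (1-w)^alpha (1-w*)^alpha,

which penalizes contacts between weakly protective opinions, while each
compartment relaxes under its own Fokker-Planck operator at rate 1/tau.
The system is advanced by Strang splitting: half an epidemic substep
(node-wise RK4), a full opinion substep (semi-implicit structure-preserving
scheme), half an epidemic substep.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from .fokker_planck import FokkerPlanckSolver
from .grid import CompartmentDensity, OpinionGrid
from .micro import OpinionParams

COMPARTMENTS = ("S", "E", "I", "R")


@dataclass(frozen=True)
class EpidemicParams:
    """Epidemiological rates and the opinion time scale.

    beta    baseline transmission rate (> 0);
    alpha   protection-efficacy exponent (>= 0; alpha = 0 removes the
            opinion feedback and recovers the classical SEIR model);
    sigma_e inverse mean latent period (> 0);
    gamma   inverse mean infectious period (> 0);
    tau     opinion relaxation time scale (> 0; tau << 1 means opinions are
            much faster than the epidemic).
    """

    beta: float = 0.4
    alpha: float = 1.0
    sigma_e: float = 0.5
    gamma: float = 1.0 / 12.0
    tau: float = 1.0

    def __post_init__(self):
        if self.beta < 0 or self.alpha < 0:
            raise ValueError("beta and alpha must be nonnegative")
        if self.sigma_e <= 0 or self.gamma <= 0 or self.tau <= 0:
            raise ValueError("sigma_e, gamma and tau must be positive")


def kappa(w, w_star, beta: float, alpha: float):
    """Contact kernel (beta/4^alpha)(1-w)^alpha (1-w*)^alpha."""
    if beta < 0 or alpha < 0:
        raise ValueError("beta and alpha must be nonnegative")
    w = np.asarray(w, dtype=float)
    w_star = np.asarray(w_star, dtype=float)
    return beta / 4.0**alpha * (1.0 - w) ** alpha * (1.0 - w_star) ** alpha


@dataclass
class KineticState:
    """The four compartment densities on a shared grid at one time."""

    grid: OpinionGrid
    f: Dict[str, np.ndarray]
    time: float = 0.0

    def __post_init__(self):
        for J in COMPARTMENTS:
            if J not in self.f:
                raise ValueError(f"missing compartment {J}")
            self.f[J] = np.asarray(self.f[J], dtype=float)
            if self.f[J].shape != (self.grid.n_nodes,):
                raise ValueError("density shape mismatch")

    def rho(self, J: str) -> float:
        return self.grid.mass(self.f[J])

    def mean(self, J: str) -> float:
        return self.grid.mean(self.f[J])

    @property
    def total_mass(self) -> float:
        return sum(self.rho(J) for J in COMPARTMENTS)

    def copy(self) -> "KineticState":
        return KineticState(self.grid, {J: self.f[J].copy() for J in COMPARTMENTS},
                            self.time)


def incidence(f_s: np.ndarray, f_i: np.ndarray, grid: OpinionGrid,
              params: EpidemicParams) -> np.ndarray:
    """Local incidence K(f_S, f_I)(w) on the grid (trapezoid quadrature).

    For alpha = 1 this coincides node-wise with the closed form
    (beta/4)(1-w) f_S(w) (1-m_I) rho_I.
    """
    contact = (1.0 - grid.nodes) ** params.alpha
    integral = grid.weights @ (contact * f_i)
    return params.beta / 4.0**params.alpha * contact * f_s * integral


def incidence_K(f_s: CompartmentDensity, f_i: CompartmentDensity,
                params: EpidemicParams) -> CompartmentDensity:
    """Density-valued incidence operator (wrapper for CompartmentDensity)."""
    if f_s.grid is not f_i.grid and f_s.grid.n_nodes != f_i.grid.n_nodes:
        raise ValueError("grid mismatch between f_S and f_I")
    return CompartmentDensity(f_s.grid,
                              incidence(f_s.values, f_i.values, f_s.grid, params))


def _epidemic_rhs(f: Dict[str, np.ndarray], grid: OpinionGrid,
                  params: EpidemicParams) -> Dict[str, np.ndarray]:
    K = incidence(f["S"], f["I"], grid, params)
    return {
        "S": -K,
        "E": K - params.sigma_e * f["E"],
        "I": params.sigma_e * f["E"] - params.gamma * f["I"],
        "R": params.gamma * f["I"],
    }


def epidemic_substep(state: KineticState, params: EpidemicParams,
                     dt: float) -> KineticState:
    """Node-wise RK4 step of the transmission/transition dynamics.

    The right-hand sides telescope node-wise, so the total density
    f_S + f_E + f_I + f_R is conserved at every node.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    f0 = state.f
    k1 = _epidemic_rhs(f0, state.grid, params)
    f1 = {J: f0[J] + 0.5 * dt * k1[J] for J in COMPARTMENTS}
    k2 = _epidemic_rhs(f1, state.grid, params)
    f2 = {J: f0[J] + 0.5 * dt * k2[J] for J in COMPARTMENTS}
    k3 = _epidemic_rhs(f2, state.grid, params)
    f3 = {J: f0[J] + dt * k3[J] for J in COMPARTMENTS}
    k4 = _epidemic_rhs(f3, state.grid, params)
    out = {J: f0[J] + dt / 6.0 * (k1[J] + 2 * k2[J] + 2 * k3[J] + k4[J])
           for J in COMPARTMENTS}
    for J in COMPARTMENTS:
        if not np.all(np.isfinite(out[J])):
            raise FloatingPointError("non-finite state in the epidemic substep")
        np.clip(out[J], 0.0, None, out=out[J])
    return KineticState(state.grid, out, state.time + dt)


class KineticSEIR:
    """Strang-split integrator of the kinetic SEIR system.

    Parameters
    ----------
    grid : OpinionGrid
    params : EpidemicParams
    opinion_params : OpinionParams or dict keyed by compartment
        Per-compartment opinion dynamics; a single object applies to all.
    drift_mode : {"linear", "nonlocal"}
    splitting : {"strang", "lie"}
    scheme : {"semi-implicit", "crank-nicolson"}
        Time scheme of the opinion substep (see
        :meth:`FokkerPlanckSolver.step`).
    """

    def __init__(self, grid: OpinionGrid, params: EpidemicParams,
                 opinion_params: OpinionParams | Dict[str, OpinionParams],
                 drift_mode: str = "linear", splitting: str = "strang",
                 scheme: str = "semi-implicit"):
        if splitting not in ("strang", "lie"):
            raise ValueError("splitting must be 'strang' or 'lie'")
        self.grid = grid
        self.params = params
        self.scheme = scheme
        if isinstance(opinion_params, OpinionParams):
            opinion_params = {J: opinion_params for J in COMPARTMENTS}
        self.opinion_params = opinion_params
        self.splitting = splitting
        self.solvers = {
            J: FokkerPlanckSolver(grid, opinion_params[J], drift_mode=drift_mode,
                                  tau=params.tau)
            for J in COMPARTMENTS
        }

    def opinion_substep(self, state: KineticState, dt: float) -> KineticState:
        rho_i = state.rho("I")
        out = {J: self.solvers[J].step(state.f[J], dt, rho_i=rho_i,
                                       scheme=self.scheme)
               for J in COMPARTMENTS}
        return KineticState(state.grid, out, state.time)

    def step(self, state: KineticState, dt: float) -> KineticState:
        if self.splitting == "lie":
            s = self.opinion_substep(state, dt)
            return epidemic_substep(s, self.params, dt)
        s = epidemic_substep(state, self.params, 0.5 * dt)
        s = self.opinion_substep(s, dt)
        s = epidemic_substep(s, self.params, 0.5 * dt)
        s.time = state.time + dt
        return s

    def run(self, init: KineticState, T: float, dt: float,
            snapshot_times: Optional[Sequence[float]] = None,
            guard: float = 1e-12):
        """Integrate to time ``T``; returns ``(observables, snapshots)``.

        ``observables`` is a DataFrame with the per-compartment mass
        fractions and mean opinions at every step; the mean of an (almost)
        empty compartment (rho < ``guard``) is carried over from the previous
        step rather than computed as 0/0.  ``snapshots`` maps requested times
        to copies of the state.
        """
        if abs(init.total_mass - 1.0) > 1e-8:
            raise ValueError("initial compartment masses must sum to 1")
        n_steps = int(round(T / dt))
        state = init.copy()
        rows = []
        means = {}
        snaps = {}
        want = sorted(snapshot_times or [])

        def record(state):
            row = {"t": state.time}
            for J in COMPARTMENTS:
                rho = state.rho(J)
                if rho >= guard:
                    means[J] = state.grid.moment(state.f[J], 1) / rho
                row[f"rho_{J}"] = rho
                row[f"m_{J}"] = means.get(J, 0.0)
            rows.append(row)

        record(state)
        if want and want[0] <= 1e-12:
            snaps[0.0] = state.copy()
            want = want[1:]
        for k in range(1, n_steps + 1):
            state = self.step(state, dt)
            record(state)
            while want and want[0] <= state.time + 1e-9:
                snaps[want[0]] = state.copy()
                want = want[1:]
        return pd.DataFrame(rows), snaps


def strang_step(state: KineticState, params: EpidemicParams,
                opinion_params: OpinionParams | Dict[str, OpinionParams],
                dt: float, drift_mode: str = "linear") -> KineticState:
    """One Strang step (functional wrapper around :class:`KineticSEIR`)."""
    model = KineticSEIR(state.grid, params, opinion_params, drift_mode=drift_mode)
    return model.step(state, dt)


def run_kinetic_seir(init: KineticState, params: EpidemicParams,
                     opinion_params: OpinionParams | Dict[str, OpinionParams],
                     T: float, dt: float, drift_mode: str = "linear",
                     splitting: str = "strang",
                     snapshot_times: Optional[Sequence[float]] = None):
    """Run the kinetic SEIR model; see :meth:`KineticSEIR.run`."""
    model = KineticSEIR(init.grid, params, opinion_params,
                        drift_mode=drift_mode, splitting=splitting)
    return model.run(init, T, dt, snapshot_times=snapshot_times)
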