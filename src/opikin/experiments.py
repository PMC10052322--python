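"""Reference experiments: initial conditions, diagnostics and one-command drivers.

Five study designs are bundled, each reproducible at ``full`` or ``desk``
(reduced particle count) scale:

``quasi-invariant``
    DSMC relaxation of the pure opinion model towards the beta steady state
    for decreasing scaling parameter eps.
``closure``
    Coupled kinetic SEIR versus the beta-closure macroscopic ODEs for fast,
    comparable and slow opinion time scales tau.
``bounded-confidence``
    Kinetic SEIR with a bounded-confidence kernel: opinion clustering and
    mass transfer from the weakly protective cluster.
``infection-driven``
    Confidence threshold switching with the infected fraction: epidemic peak
    ordered by the switch level C_I.
``polarization``
    Terminal recovered fraction across susceptible polarization levels nu_S.
"""

from __future__ import annotations

import json
import time as _time
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from . import __version__
from .dsmc import (PiecewiseUniform, empirical_density,
                   run_quasi_invariant, shifted_uniform_spec, uniform_spec)
from .equilibrium import BetaEquilibrium
from .grid import CompartmentDensity, OpinionGrid
from .macro import (integrate_macro, macro_state,
                    macro_trajectory_frame, polarization_sweep)
from .micro import InteractionKernel, OpinionParams
from .seir import COMPARTMENTS, EpidemicParams, KineticState, run_kinetic_seir

# ----------------------------------------------------------------------
# initial conditions
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class InitialConditionSpec:
    """Named piecewise-uniform initial state of the four compartments.

    ``segments[J]`` are the (lo, hi, height) pieces of a *normalized*
    density; the compartment density is ``rho0[J]`` times that shape.
    """

    name: str
    rho0: Dict[str, float]
    segments: Dict[str, tuple]

    def __post_init__(self):
        if abs(sum(self.rho0.values()) - 1.0) > 1e-10:
            raise ValueError("compartment masses must sum to 1")


def _split_spec(name: str, rho0: Dict[str, float],
                susceptible_broad: bool) -> InitialConditionSpec:
    g = ((-1.0, 1.0, 0.5),) if susceptible_broad else ((-1.0, 0.0, 1.0),)
    h = ((0.0, 1.0, 1.0),)
    return InitialConditionSpec(name, rho0, {"S": g, "E": g, "I": h, "R": h})


def initial_condition(name: str, rho0: Optional[Dict[str, float]] = None
                      ) -> InitialConditionSpec:
    """Registry of the bundled initial conditions.

    ``uniform``        all compartments uniform on [-1, 1] (mean 0);
    ``shifted``        all compartments uniform on [-0.6, 1] (mean 0.2);
    ``split``          S, E uniform on [-1, 0], I, R uniform on [0, 1]
                       (susceptibles sceptical, infected aware);
    ``mixed``          S, E uniform on [-1, 1], I, R uniform on [0, 1].
    Default masses are (0.97, 0.01, 0.01, 0.01); ``rho0`` overrides them.
    """
    rho0 = dict(rho0 or {"S": 0.97, "E": 0.01, "I": 0.01, "R": 0.01})
    if name == "uniform":
        seg = {J: ((-1.0, 1.0, 0.5),) for J in COMPARTMENTS}
        return InitialConditionSpec(name, rho0, seg)
    if name == "shifted":
        seg = {J: ((-0.6, 1.0, 0.625),) for J in COMPARTMENTS}
        return InitialConditionSpec(name, rho0, seg)
    if name == "split":
        return _split_spec(name, rho0, susceptible_broad=False)
    if name == "mixed":
        return _split_spec(name, rho0, susceptible_broad=True)
    raise ValueError(f"unknown initial condition {name!r}")


def build_initial_condition(spec: InitialConditionSpec,
                            grid: OpinionGrid) -> KineticState:
    """Project an :class:`InitialConditionSpec` onto a grid as a KineticState."""
    f = {}
    for J in COMPARTMENTS:
        shape = grid.project_piecewise_uniform(spec.segments[J], mass=1.0)
        f[J] = spec.rho0[J] * shape
    return KineticState(grid, f, time=0.0)


# ----------------------------------------------------------------------
# diagnostics
# ----------------------------------------------------------------------
def l1_distance(f, g, weights: Optional[np.ndarray] = None) -> float:
    """Discrete L1 distance between two densities on a shared grid/binning.

    Accepts :class:`CompartmentDensity` pairs (shared grid) or raw arrays
    with explicit quadrature ``weights``.
    """
    if isinstance(f, CompartmentDensity) and isinstance(g, CompartmentDensity):
        if f.grid.n_nodes != g.grid.n_nodes:
            raise ValueError("grid mismatch")
        return f.grid.l1_distance(f.values, g.values)
    f = np.asarray(f, dtype=float)
    g = np.asarray(g, dtype=float)
    if f.shape != g.shape:
        raise ValueError("shape mismatch")
    if weights is None:
        raise ValueError("raw arrays need quadrature weights")
    return float(np.asarray(weights) @ np.abs(f - g))


def cluster_count(density, prominence: float = 0.05) -> int:
    """Number of interior local maxima with relative prominence above threshold.

    ``prominence`` is relative to the density maximum (default 5%).
    """
    values = density.values if isinstance(density, CompartmentDensity) else np.asarray(density)
    peak_height = values.max()
    if peak_height <= 0:
        return 0
    peaks, _ = find_peaks(values, prominence=prominence * peak_height)
    return int(len(peaks))


def l1_to_beta(ensemble, eq: BetaEquilibrium, grid: Optional[OpinionGrid] = None,
               bins: int = 100) -> float:
    """L1 distance of a particle ensemble's histogram to a beta steady state.

    Uses cell-averaged beta values (regularized incomplete beta function), so
    boundary-divergent polarized profiles are compared through integrable
    cell masses rather than divergent point values.
    """
    if grid is not None:
        hist = empirical_density(ensemble, grid)
        return grid.l1_distance(hist.values, eq.cell_averages(grid))
    edges = np.linspace(-1.0, 1.0, bins + 1)
    counts, _ = np.histogram(ensemble.opinions, bins=edges)
    width = 2.0 / bins
    emp = counts / (ensemble.n * width)
    ref = eq.cell_masses(edges) / width
    return float(np.sum(np.abs(emp - ref)) * width)


# ----------------------------------------------------------------------
# drivers
# ----------------------------------------------------------------------
EXPERIMENTS = ("quasi-invariant", "closure", "bounded-confidence",
               "infection-driven", "polarization")


def _manifest(name: str, scale: str, seed: int, config: dict, t0: float) -> dict:
    return {
        "experiment": name,
        "scale": scale,
        "seed": seed,
        "version": __version__,
        "config": config,
        "runtime_s": round(_time.monotonic() - t0, 3),
    }


def run_experiment(name: str, scale: str = "desk", seed: int = 0,
                   outdir: Optional[str | Path] = None) -> dict:
    """Run one bundled experiment; returns tables plus a run manifest.

    ``scale='desk'`` reduces the DSMC particle count from 1e6 to 1e5 (all
    grid-based runs already complete at full resolution).  If ``outdir`` is
    given every table is written as CSV plus a ``manifest.json``.
    """
    t0 = _time.monotonic()
    if name == "quasi-invariant":
        out = _run_quasi_invariant(scale, seed)
    elif name == "closure":
        out = _run_closure(scale, seed)
    elif name == "bounded-confidence":
        out = _run_bounded_confidence(scale, seed)
    elif name == "infection-driven":
        out = _run_infection_driven(scale, seed)
    elif name == "polarization":
        out = _run_polarization(scale, seed)
    else:
        raise ValueError(f"unknown experiment {name!r}; choose from {EXPERIMENTS}")
    out["manifest"] = _manifest(name, scale, seed, out.pop("config", {}), t0)
    if outdir is not None:
        write_outputs(out, outdir)
    return out


def write_outputs(result: dict, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = []
    for key, value in result.items():
        if isinstance(value, pd.DataFrame):
            path = outdir / f"{key}.csv"
            value.to_csv(path, index=False)
            files.append(path.name)
    manifest = dict(result.get("manifest", {}))
    manifest["files"] = files
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))


def _run_quasi_invariant(scale: str, seed: int) -> dict:
    n = 10**6 if scale == "full" else 10**5
    horizon, bins = 5.0, 100
    rows = []
    density_tables = {}
    cases = [(0.25, uniform_spec(), 0.0), (2.0, uniform_spec(), 0.0),
             (0.25, shifted_uniform_spec(), 0.2), (2.0, shifted_uniform_spec(), 0.2)]
    for i, (nu, spec, m0) in enumerate(cases):
        eq = BetaEquilibrium(m0, nu)
        for eps in (1e-1, 1e-3):
            params = OpinionParams(lam=1.0, sigma2=nu, kernel=InteractionKernel())
            ens, _ = run_quasi_invariant(spec, n, eps, params, horizon,
                                         seed=seed + i)
            dist = l1_to_beta(ens, eq, bins=bins)
            rows.append({"nu": nu, "m0": m0, "epsilon": eps,
                         "l1_to_beta": dist, "mean": ens.mean,
                         "variance": ens.variance})
            edges = np.linspace(-1, 1, bins + 1)
            counts, _ = np.histogram(ens.opinions, bins=edges)
            density_tables[f"density_nu{nu}_m{m0}_eps{eps}"] = pd.DataFrame({
                "w": 0.5 * (edges[:-1] + edges[1:]),
                "empirical": counts / (n * 2.0 / bins),
                "beta": eq.cell_masses(edges) / (2.0 / bins),
            })
    out = {"l1_table": pd.DataFrame(rows),
           "config": {"n_particles": n, "T": horizon, "bins": bins}}
    out.update(density_tables)
    return out


_EPI = dict(beta=0.4, sigma_e=0.5, gamma=1.0 / 12.0)


def _run_closure(scale: str, seed: int) -> dict:
    grid = OpinionGrid(201)
    opinion = OpinionParams(lam=1.0, sigma2=1e-3, kernel=InteractionKernel())
    spec = initial_condition("split")
    init = build_initial_condition(spec, grid)
    T, dt = 100.0, 1e-1
    tables = {}
    for tau in (1e-5, 1.0, 100.0):
        params = EpidemicParams(alpha=1.0, tau=tau, **_EPI)
        obs, _ = run_kinetic_seir(init, params, opinion, T, dt, drift_mode="linear")
        tables[f"kinetic_tau{tau:g}"] = obs
    y0 = macro_state([init.rho(J) for J in COMPARTMENTS],
                     [init.mean(J) for J in COMPARTMENTS])
    times, Y = integrate_macro(y0, EpidemicParams(alpha=1.0, **_EPI),
                               opinion.nu, T, dt)
    tables["macro"] = macro_trajectory_frame(times, Y)
    tables["config"] = {"T": T, "dt": dt, "n_nodes": 201, "nu": opinion.nu}
    return tables


def _run_bounded_confidence(scale: str, seed: int) -> dict:
    grid = OpinionGrid(201)
    tables = {}
    for delta in (0.5, 0.25):
        kernel = InteractionKernel(kind="bounded_confidence", delta=delta)
        opinion = OpinionParams(lam=1.0, sigma2=1e-3, kernel=kernel)
        params = EpidemicParams(alpha=1.0, tau=1.0, **_EPI)
        init = build_initial_condition(initial_condition("mixed"), grid)
        obs, snaps = run_kinetic_seir(init, params, opinion, 100.0, 1e-1,
                                      drift_mode="nonlocal",
                                      snapshot_times=[100.0])
        tables[f"observables_delta{delta}"] = obs
        final = snaps[100.0]
        tables[f"density_delta{delta}"] = pd.DataFrame(
            {"w": grid.nodes, **{f"f_{J}": final.f[J] for J in COMPARTMENTS}})
    tables["config"] = {"T": 100.0, "dt": 1e-1, "n_nodes": 201}
    return tables


def _run_infection_driven(scale: str, seed: int) -> dict:
    grid = OpinionGrid(201)
    tables = {}
    rows = []
    rho0 = {"S": 1.0 - 3e-3, "E": 1e-3, "I": 1e-3, "R": 1e-3}
    for c_i in (0.01, 0.025, 0.05):
        kernel = InteractionKernel(kind="infection_driven", delta1=0.1,
                                   delta2=0.5, c_i=c_i)
        opinion = OpinionParams(lam=1.0, sigma2=1e-3, kernel=kernel)
        params = EpidemicParams(alpha=1.0, tau=1.0, **_EPI)
        init = build_initial_condition(initial_condition("mixed", rho0), grid)
        obs, _ = run_kinetic_seir(init, params, opinion, 200.0, 1e-1,
                                  drift_mode="nonlocal")
        tables[f"observables_ci{c_i}"] = obs
        rows.append({"C_I": c_i, "peak_rho_I": obs["rho_I"].max(),
                     "final_rho_R": obs["rho_R"].iloc[-1]})
    tables["summary"] = pd.DataFrame(rows)
    tables["config"] = {"T": 200.0, "dt": 1e-1, "n_nodes": 201, "rho0": rho0}
    return tables


def _run_polarization(scale: str, seed: int) -> dict:
    params = EpidemicParams(alpha=1.0, **_EPI)
    nu_grid = np.linspace(0.0, 10.0, 11)
    tables = {}
    for m0 in (-0.5, 0.5):
        tables[f"sweep_m0_{m0:+g}"] = polarization_sweep(nu_grid, m0, params)
    tables["config"] = {"T": 300.0, "dt": 1e-2, "nu_grid": nu_grid.tolist()}
    return tables
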