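"""TOML run-configuration parsing for the command-line interface.

A configuration file declares epidemic parameters, per-compartment opinion
parameters (with a ``default`` fallback), an initial condition, grid and
time resolutions and a seed, e.g.::

    [run]
    T = 100.0
    dt = 0.1
    n_nodes = 201
    seed = 1

    [epidemic]
    beta = 0.4
    alpha = 1.0
    sigma_e = 0.5
    gamma = 0.0833333333
    tau = 1.0

    [opinion.default]
    lam = 1.0
    sigma2 = 1e-3
    kernel = { kind = "bounded_confidence", delta = 0.5 }

    [init]
    name = "split"        # uniform | shifted | split | mixed
    rho0 = { S = 0.97, E = 0.01, I = 0.01, R = 0.01 }
"""

from __future__ import annotations

import tomllib
from pathlib import Path
from typing import Dict

from .experiments import build_initial_condition, initial_condition
from .grid import OpinionGrid
from .micro import InteractionKernel, OpinionParams
from .seir import COMPARTMENTS, EpidemicParams


def load_config(path: str | Path) -> dict:
    with open(path, "rb") as fh:
        return tomllib.load(fh)


def parse_kernel(section: dict) -> InteractionKernel:
    return InteractionKernel(**section)


def parse_opinion(section: dict) -> Dict[str, OpinionParams]:
    """Per-compartment opinion parameters with a ``default`` fallback."""
    default = dict(section.get("default", {}))
    out = {}
    for J in COMPARTMENTS:
        entry = {**default, **section.get(J, {})}
        kernel = parse_kernel(entry.pop("kernel", {}))
        out[J] = OpinionParams(kernel=kernel, **entry)
    return out


def parse_epidemic(section: dict) -> EpidemicParams:
    return EpidemicParams(**section)


def parse_run(config: dict):
    """Return (run dict, grid, epidemic params, opinion params, initial state)."""
    run = dict(config.get("run", {}))
    grid = OpinionGrid(int(run.get("n_nodes", 201)))
    epidemic = parse_epidemic(config.get("epidemic", {}))
    opinion = parse_opinion(config.get("opinion", {"default": {}}))
    init_cfg = dict(config.get("init", {"name": "split"}))
    spec = initial_condition(init_cfg.get("name", "split"),
                             init_cfg.get("rho0"))
    state = build_initial_condition(spec, grid)
    return run, grid, epidemic, opinion, state
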