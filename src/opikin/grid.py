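"""Discretization of the opinion interval [-1, 1].

The grid is vertex-centred: ``n_nodes`` equispaced nodes with the endpoints
exactly at -1 and 1.  Each node owns a finite-volume cell of width ``dw``
(half width at the two boundary nodes), so the cell widths coincide with the
trapezoidal quadrature weights.  All moments, distances and normalizations in
the package use this single quadrature rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class OpinionGrid:
    """Equispaced grid on the opinion interval [-1, 1].

    Parameters
    ----------
    n_nodes : int
        Number of nodes (>= 3).  Nodes are ``w_i = -1 + i * dw`` with
        ``dw = 2 / (n_nodes - 1)``.
    """

    def __init__(self, n_nodes: int = 201):
        if n_nodes < 3:
            raise ValueError("OpinionGrid needs at least 3 nodes")
        self.n_nodes = int(n_nodes)
        self.nodes = np.linspace(-1.0, 1.0, self.n_nodes)
        self.dw = 2.0 / (self.n_nodes - 1)
        self.midpoints = 0.5 * (self.nodes[:-1] + self.nodes[1:])
        # trapezoidal weights == finite-volume cell widths (half cells at +-1)
        self.weights = np.full(self.n_nodes, self.dw)
        self.weights[0] = self.weights[-1] = 0.5 * self.dw
        # edges of the node-centred cells, clipped to the domain
        self.cell_edges = np.concatenate(([-1.0], self.midpoints, [1.0]))

    # ------------------------------------------------------------------
    # quadrature
    # ------------------------------------------------------------------
    def integrate(self, values: np.ndarray) -> float:
        return float(self.weights @ np.asarray(values))

    def mass(self, values: np.ndarray) -> float:
        return self.integrate(values)

    def moment(self, values: np.ndarray, order: int = 1) -> float:
        """Raw moment ``int w^r f(w) dw`` (not normalized by the mass)."""
        return float(self.weights @ (self.nodes**order * np.asarray(values)))

    def mean(self, values: np.ndarray) -> float:
        """Mass-normalized mean opinion of a density."""
        rho = self.mass(values)
        if rho <= 0.0:
            raise ValueError("mean undefined for a zero-mass density")
        return self.moment(values, 1) / rho

    def l1_distance(self, f: np.ndarray, g: np.ndarray) -> float:
        return float(self.weights @ np.abs(np.asarray(f) - np.asarray(g)))

    def normalize(self, values: np.ndarray, mass: float = 1.0) -> np.ndarray:
        total = self.mass(values)
        if total <= 0.0:
            raise ValueError("cannot normalize a nonpositive-mass density")
        return np.asarray(values) * (mass / total)

    # ------------------------------------------------------------------
    # projection of piecewise-constant densities
    # ------------------------------------------------------------------
    def project_piecewise_uniform(self, segments, mass: float | None = None) -> np.ndarray:
        """Nodal values of a piecewise-constant density.

        ``segments`` is an iterable of ``(lo, hi, height)``.  At a node that
        coincides with a jump of the density the value is the midpoint of the
        two one-sided limits, which makes the trapezoidal mass and mean of the
        projection exact for jumps located on grid nodes.  If ``mass`` is
        given the result is rescaled to that discrete mass.
        """
        values = np.zeros(self.n_nodes)
        tol = 1e-12
        for lo, hi, height in segments:
            if lo < -1.0 - tol or hi > 1.0 + tol or hi <= lo:
                raise ValueError(f"invalid segment ({lo}, {hi})")
            inside = (self.nodes > lo + tol) & (self.nodes < hi - tol)
            values[inside] += height
            on_edge = (np.abs(self.nodes - lo) <= tol) | (np.abs(self.nodes - hi) <= tol)
            values[on_edge] += 0.5 * height
        # domain endpoints are not jumps if the segment covers them fully
        if values[0] > 0 and any(abs(lo - (-1.0)) <= tol for lo, hi, h in segments):
            for lo, hi, height in segments:
                if abs(lo - (-1.0)) <= tol:
                    values[0] += 0.5 * height
        if values[-1] > 0 and any(abs(hi - 1.0) <= tol for lo, hi, h in segments):
            for lo, hi, height in segments:
                if abs(hi - 1.0) <= tol:
                    values[-1] += 0.5 * height
        if mass is not None:
            values = self.normalize(values, mass)
        return values

    def __repr__(self) -> str:  # pragma: no cover
        return f"OpinionGrid(n_nodes={self.n_nodes})"


@dataclass
class CompartmentDensity:
    """Nonnegative opinion density of one compartment on an :class:`OpinionGrid`."""

    grid: OpinionGrid
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.n_nodes,):
            raise ValueError("density values must match the grid size")
        if np.any(self.values < -1e-13):
            raise ValueError("density values must be nonnegative")

    @property
    def mass(self) -> float:
        return self.grid.mass(self.values)

    @property
    def mean(self) -> float:
        return self.grid.mean(self.values)

    def moment(self, order: int) -> float:
        return self.grid.moment(self.values, order)

    def copy(self) -> "CompartmentDensity":
        return CompartmentDensity(self.grid, self.values.copy())
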