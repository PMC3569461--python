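"""Pseudo-unipolar electrogram forward model (large volume conductor).

The extracellular potential at an electrode a small distance off the tissue
plane is

    phi_e(t) = K * sum_elements [ -grad(Vm) . grad'(1/r) ] dV

where grad' acts on the source coordinates, r is the source-electrode
distance and K (which bundles the intra/extracellular conductivity ratio)
is set to 1, so amplitudes are in arbitrary units; every downstream
analysis (dominant frequency, organization index, morphology classes) is
amplitude-scale-free.

Because the nodal-summation integral is linear in Vm, each electrode
reduces to a fixed weight vector ("lead field") over the grid nodes;
electrograms are then inner products per sample, which also lets the
tissue solver accumulate EGMs on the fly without storing the Vm history.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .regions import TissueGrid

__all__ = [
    "Electrode",
    "EGMTrace",
    "egm_weights",
    "compute_egm",
    "compute_egm_array",
    "electrode_lattice",
]

DEFAULT_OFFSET_UM = 200.0  # 0.2 mm off the tissue surface


@dataclass(frozen=True)
class Electrode:
    """Point electrode at (x, y) um, ``offset`` um above the tissue plane."""

    x: float
    y: float = 0.0
    offset: float = DEFAULT_OFFSET_UM

    def __post_init__(self) -> None:
        if self.offset <= 0:
            raise ValueError("electrode offset must be positive "
                             "(never inside the tissue plane)")


@dataclass
class EGMTrace:
    """Sampled extracellular potential (arbitrary K-scaled units)."""

    t: np.ndarray
    phi: np.ndarray
    electrode: Electrode

    def __post_init__(self) -> None:
        if len(self.t) != len(self.phi):
            raise ValueError("t and phi must have equal length")


def _node_coords(grid: TissueGrid) -> tuple[np.ndarray, np.ndarray]:
    n = grid.n_nodes
    if grid.is_1d:
        x = np.arange(n) * grid.dx
        y = np.zeros(n)
    else:
        nx, NY = grid.dims
        ix = np.arange(n) % nx
        iy = np.arange(n) // nx
        x, y = ix * grid.dx, iy * grid.dx
    return x, y


def egm_weights(grid: TissueGrid, electrodes) -> np.ndarray:
    """Lead-field matrix W (n_electrodes, N): phi_e = W @ Vm.

    The Vm gradient is formed by central differences (one-sided at
    boundaries) and dotted with grad'(1/r); the volume element is the node
    area times a wall thickness of one node spacing (monolayer tissue).
    """
    n = grid.n_nodes
    x, y = _node_coords(grid)
    dx = grid.dx
    dvol = dx ** 3  # node volume, um^3 (monolayer: thickness = dx)
    W = np.zeros((len(electrodes), n))
    for k, el in enumerate(electrodes):
        rx, ry, rz = x - el.x, y - el.y, -el.offset
        r2 = rx * rx + ry * ry + rz * rz
        r = np.sqrt(r2)
        if np.any(r < 1e-9):
            raise ValueError("electrode coincides with a grid node (r = 0)")
        # -grad(Vm) . grad'(1/r) = grad(Vm) . (x_node - p)/r^3
        cx = rx / (r2 * r) * dvol
        cy = ry / (r2 * r) * dvol
        # distribute the central-difference gradient onto neighbor weights
        w = np.zeros(n)
        if grid.is_1d:
            periodic = grid.topology == "ring"
            for i in range(n):
                ip, im = i + 1, i - 1
                if periodic:
                    ip %= n
                    im %= n
                    h = 2.0 * dx
                elif ip >= n:
                    ip, im, h = i, i - 1, dx
                elif im < 0:
                    ip, im, h = i + 1, i, dx
                else:
                    h = 2.0 * dx
                w[ip] += cx[i] / h
                w[im] -= cx[i] / h
        else:
            nx, NY = grid.dims
            ix = np.arange(n) % nx
            iy = np.arange(n) // nx
            for (ci, comp, imax) in ((cx, ix, nx), (cy, iy, NY)):
                step = 1 if comp is ix else nx
                up = np.where(comp < imax - 1, step, 0)
                dn = np.where(comp > 0, -step, 0)
                h = np.where((up != 0) & (dn != 0), 2.0 * dx, dx)
                idx = np.arange(n)
                np.add.at(w, idx + up, ci / h)
                np.add.at(w, idx + dn, -ci / h)
        W[k] = w
    return W


def compute_egm(result, grid: TissueGrid, electrode: Electrode) -> EGMTrace:
    """Electrogram at one electrode from a stored Vm history."""
    if result.vm is None:
        raise ValueError("simulation result has no stored Vm history; "
                         "pass egm_weights to run() instead")
    W = egm_weights(grid, [electrode])
    phi = result.vm.astype(float) @ W[0]
    return EGMTrace(t=result.t.copy(), phi=phi, electrode=electrode)


def electrode_lattice(grid: TissueGrid, spacing_um: float,
                      offset: float = DEFAULT_OFFSET_UM,
                      margin_um: float | None = None) -> list[Electrode]:
    """Regular electrode lattice over the tissue footprint."""
    if margin_um is None:
        margin_um = spacing_um / 2.0
    x, y = _node_coords(grid)
    xs = np.arange(margin_um, x.max() - margin_um + 1e-9, spacing_um)
    if grid.is_1d:
        return [Electrode(xc, 0.0, offset) for xc in xs]
    ys = np.arange(margin_um, y.max() - margin_um + 1e-9, spacing_um)
    return [Electrode(xc, yc, offset) for yc in ys for xc in xs]


def compute_egm_array(result, grid: TissueGrid, spacing_um: float,
                      offset: float = DEFAULT_OFFSET_UM) -> list[EGMTrace]:
    """Electrograms over a regular lattice (one EGMTrace per electrode)."""
    electrodes = electrode_lattice(grid, spacing_um, offset)
    W = egm_weights(grid, electrodes)
    phi = result.vm.astype(float) @ W.T
    return [
        EGMTrace(t=result.t.copy(), phi=phi[:, k], electrode=el)
        for k, el in enumerate(electrodes)
    ]
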