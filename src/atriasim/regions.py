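"""Synthetic atrial tissue geometries: regions, fibers, conductivities.

Desk-scale stand-ins for the anatomical regions of the human atria.  Each
geometry (cable, sheet, ring, strip sheet) carries per-node region labels,
unit fiber vectors and longitudinal/transverse conductivities so that the
downstream monodomain solver sees the same region/conductivity/anisotropy
semantics a full anatomical model would provide.

Conductivities are a pure lookup of the published per-region calibration:
very fast crista terminalis (CT) bundles down to the very slow sinoatrial
node (SAN).  Anisotropy is 1:9 (transverse:longitudinal) in the CT, 1:2 in
the working myocardium and the other fast bundles, and isotropic in the SAN
and the right-atrial isthmus.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

__all__ = [
    "RegionLabel",
    "TissueGrid",
    "LONGITUDINAL_CONDUCTIVITY",
    "ANISOTROPY_RATIO",
    "CELL_VARIANT",
    "conductivities_for",
    "build_cable",
    "build_sheet",
    "build_ring",
    "build_strip_sheet",
    "write_grid",
    "read_grid",
]

DX_MIN_UM = 300.0
DX_MAX_UM = 700.0


class RegionLabel(Enum):
    """Atrial region labels carried by every grid node."""

    CT = "CT"            # crista terminalis
    BB = "BB"            # Bachmann's bundle
    PM = "PM"            # pectinate muscles
    FO_RIM = "FO_RIM"    # limbus of the fossa ovalis
    PV = "PV"            # pulmonary veins
    ISTHMUS = "ISTHMUS"  # right atrial isthmus
    SAN = "SAN"          # sinoatrial node
    AWM = "AWM"          # atrial working myocardium
    APG = "APG"          # appendages
    AVR = "AVR"          # atrioventricular rings


#: Longitudinal conductivity per region, S/m.
LONGITUDINAL_CONDUCTIVITY: dict[RegionLabel, float] = {
    RegionLabel.CT: 0.7,
    RegionLabel.BB: 0.5,
    RegionLabel.PM: 0.5,
    RegionLabel.FO_RIM: 0.5,
    RegionLabel.PV: 0.15,
    RegionLabel.ISTHMUS: 0.1,
    RegionLabel.SAN: 0.05,
    RegionLabel.AWM: 0.2,
    # Appendages and AV rings are part of the working myocardium
    # conductivity class (no separate row in the calibration table).
    RegionLabel.APG: 0.2,
    RegionLabel.AVR: 0.2,
}

#: Transverse:longitudinal conductivity ratio per region.
ANISOTROPY_RATIO: dict[RegionLabel, float] = {
    RegionLabel.CT: 1.0 / 9.0,
    RegionLabel.BB: 0.5,
    RegionLabel.PM: 0.5,
    RegionLabel.FO_RIM: 0.5,
    RegionLabel.PV: 0.5,
    RegionLabel.AWM: 0.5,
    RegionLabel.APG: 0.5,
    RegionLabel.AVR: 0.5,
    RegionLabel.SAN: 1.0,
    RegionLabel.ISTHMUS: 1.0,
}

#: Electrophysiological cell variant assigned to each region.  Only CT, PM,
#: APG, AVR and AWM have distinct ionic parameter sets; the remaining
#: structures default to the working-myocardium (AWM) variant and can be
#: overridden in configuration.
CELL_VARIANT: dict[RegionLabel, RegionLabel] = {
    RegionLabel.CT: RegionLabel.CT,
    RegionLabel.PM: RegionLabel.PM,
    RegionLabel.APG: RegionLabel.APG,
    RegionLabel.AVR: RegionLabel.AVR,
    RegionLabel.AWM: RegionLabel.AWM,
    RegionLabel.BB: RegionLabel.AWM,
    RegionLabel.FO_RIM: RegionLabel.AWM,
    RegionLabel.PV: RegionLabel.AWM,
    RegionLabel.ISTHMUS: RegionLabel.AWM,
    RegionLabel.SAN: RegionLabel.AWM,
}


def conductivities_for(region: RegionLabel) -> tuple[float, float]:
    """Return (sigma_l, sigma_t) in S/m for a region."""
    sl = LONGITUDINAL_CONDUCTIVITY[region]
    return sl, sl * ANISOTROPY_RATIO[region]


@dataclass
class TissueGrid:
    """Structured tissue geometry.

    Nodes are node-centered with 0-based indices; the physical position of
    node (ix, iy) is (ix*dx, iy*dx).  For 1D topologies (cable, ring)
    ``dims = (n,)``; for sheets ``dims = (nx, ny)`` and the flat node index
    is ``iy*nx + ix``.  ``fiber`` holds per-node unit vectors in the tissue
    plane; ``sigma_l``/``sigma_t`` are conductivities along and across the
    fiber, S/m.
    """

    dims: tuple[int, ...]
    dx: float  # node spacing, um
    topology: str  # {"cable", "sheet", "ring"}
    region: np.ndarray = field(repr=False)  # (N,) int codes into REGION_ORDER
    fiber: np.ndarray = field(repr=False)   # (N, 2) unit vectors
    sigma_l: np.ndarray = field(repr=False)  # (N,) S/m
    sigma_t: np.ndarray = field(repr=False)  # (N,) S/m

    def __post_init__(self) -> None:
        n = self.n_nodes
        for name in ("region", "sigma_l", "sigma_t"):
            arr = getattr(self, name)
            if arr.shape != (n,):
                raise ValueError(f"{name} must have shape ({n},), got {arr.shape}")
        if self.fiber.shape != (n, 2):
            raise ValueError(f"fiber must have shape ({n}, 2)")
        norms = np.linalg.norm(self.fiber, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-12):
            raise ValueError("fiber vectors must be unit norm")
        if np.any(self.sigma_t <= 0) or np.any(self.sigma_l < self.sigma_t - 1e-15):
            raise ValueError("require sigma_l >= sigma_t > 0")

    @property
    def n_nodes(self) -> int:
        return int(np.prod(self.dims))

    @property
    def is_1d(self) -> bool:
        return len(self.dims) == 1

    def region_labels(self) -> list[RegionLabel]:
        return [REGION_ORDER[c] for c in self.region]

    def node_position(self, i: int) -> tuple[float, ...]:
        """Physical position of flat node index ``i`` in um."""
        if self.is_1d:
            return (i * self.dx,)
        nx = self.dims[0]
        return ((i % nx) * self.dx, (i // nx) * self.dx)


REGION_ORDER: tuple[RegionLabel, ...] = tuple(RegionLabel)
_REGION_CODE = {r: i for i, r in enumerate(REGION_ORDER)}


def _check_dx(dx: float) -> None:
    if not (DX_MIN_UM <= dx <= DX_MAX_UM):
        raise ValueError(
            f"dx={dx} um outside the validated discretization range "
            f"[{DX_MIN_UM:.0f}, {DX_MAX_UM:.0f}] um"
        )


def _uniform_arrays(n: int, region: RegionLabel, fiber_vec: np.ndarray):
    sl, st = conductivities_for(region)
    return (
        np.full(n, _REGION_CODE[region], dtype=np.int32),
        np.tile(fiber_vec, (n, 1)).astype(float),
        np.full(n, sl),
        np.full(n, st),
    )


def build_cable(n_nodes: int, dx: float, region: RegionLabel) -> TissueGrid:
    """1D cable with the fiber along the cable axis."""
    if n_nodes < 3:
        raise ValueError("a cable needs at least 3 nodes (Laplacian interior)")
    _check_dx(dx)
    reg, fib, sl, st = _uniform_arrays(n_nodes, region, np.array([1.0, 0.0]))
    return TissueGrid((n_nodes,), dx, "cable", reg, fib, sl, st)


def build_ring(n_nodes: int, dx: float, region: RegionLabel) -> TissueGrid:
    """Periodic 1D domain (circumference n_nodes*dx) with tangential fiber."""
    if n_nodes < 3:
        raise ValueError("a ring needs at least 3 nodes")
    _check_dx(dx)
    reg, fib, sl, st = _uniform_arrays(n_nodes, region, np.array([1.0, 0.0]))
    return TissueGrid((n_nodes,), dx, "ring", reg, fib, sl, st)


def build_sheet(
    nx: int, ny: int, dx: float, region: RegionLabel, fiber_angle: float = 0.0
) -> TissueGrid:
    """2D sheet with a uniform fiber angle (degrees, from the x axis)."""
    if nx < 3 or ny < 3:
        raise ValueError("a sheet needs at least 3x3 nodes")
    _check_dx(dx)
    ang = np.deg2rad(fiber_angle)
    fvec = np.array([np.cos(ang), np.sin(ang)])
    reg, fib, sl, st = _uniform_arrays(nx * ny, region, fvec)
    return TissueGrid((nx, ny), dx, "sheet", reg, fib, sl, st)


def build_strip_sheet(
    nx: int,
    ny: int,
    dx: float,
    base_region: RegionLabel,
    strip_region: RegionLabel,
    strip_rows: range,
    fiber_angle: float = 0.0,
) -> TissueGrid:
    """Sheet with an embedded horizontal strip of a second region.

    The strip (e.g. CT inside AWM) occupies the given row range; its fiber
    runs along the strip (x axis), emulating the longitudinal orientation of
    the fast bundles, while the base region keeps ``fiber_angle``.
    """
    rows = list(strip_rows)
    if not rows:
        raise ValueError("strip_rows is empty")
    if min(rows) < 0 or max(rows) >= ny:
        raise ValueError("strip_rows outside the sheet")
    grid = build_sheet(nx, ny, dx, base_region, fiber_angle)
    sl, st = conductivities_for(strip_region)
    mask = np.isin(np.arange(nx * ny) // nx, rows)
    grid.region[mask] = _REGION_CODE[strip_region]
    grid.fiber[mask] = np.array([1.0, 0.0])
    grid.sigma_l[mask] = sl
    grid.sigma_t[mask] = st
    return grid


# ---------------------------------------------------------------------------
# text serialization: structured header + columnar table

def write_grid(grid: TissueGrid, path_or_buf) -> None:
    """Serialize a grid as a text header plus a columnar numeric table."""
    buf = io.StringIO()
    buf.write(f"# atriasim grid v1\n")
    buf.write(f"dims {' '.join(str(d) for d in grid.dims)}\n")
    buf.write(f"dx_um {grid.dx!r}\n")
    buf.write(f"topology {grid.topology}\n")
    buf.write("# region fiber_x fiber_y sigma_l sigma_t\n")
    for i in range(grid.n_nodes):
        buf.write(
            f"{REGION_ORDER[grid.region[i]].value} "
            f"{float(grid.fiber[i, 0])!r} {float(grid.fiber[i, 1])!r} "
            f"{float(grid.sigma_l[i])!r} {float(grid.sigma_t[i])!r}\n"
        )
    text = buf.getvalue()
    if hasattr(path_or_buf, "write"):
        path_or_buf.write(text)
    else:
        with open(path_or_buf, "w") as fh:
            fh.write(text)


def read_grid(path_or_buf) -> TissueGrid:
    """Read a grid written by :func:`write_grid`."""
    if hasattr(path_or_buf, "read"):
        lines = path_or_buf.read().splitlines()
    else:
        with open(path_or_buf) as fh:
            lines = fh.read().splitlines()
    header: dict[str, str] = {}
    rows = []
    for line in lines:
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key = line.split()[0]
        if key in ("dims", "dx_um", "topology"):
            header[key] = line.split(None, 1)[1]
        else:
            rows.append(line.split())
    dims = tuple(int(x) for x in header["dims"].split())
    dx = float(header["dx_um"])
    n = int(np.prod(dims))
    if len(rows) != n:
        raise ValueError(f"expected {n} node rows, got {len(rows)}")
    region = np.array([_REGION_CODE[RegionLabel(r[0])] for r in rows], dtype=np.int32)
    fiber = np.array([[float(r[1]), float(r[2])] for r in rows])
    sigma_l = np.array([float(r[3]) for r in rows])
    sigma_t = np.array([float(r[4]) for r in rows])
    return TissueGrid(dims, dx, header["topology"], region, fiber, sigma_l, sigma_t)
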