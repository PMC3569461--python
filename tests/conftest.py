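"""Shared fixtures: expensive simulations computed once per session."""

import numpy as np
import pytest

from atriasim.cell import PacingProtocol, make_cell_params, pace_cell


REGIONS = ("CT", "PM", "APG", "AVR", "AWM")


def dense_fd_oracle(grid, sv, cm_area):
    """Brute-force dense finite-difference matrix for a 2D sheet.

    Independent naive construction: loops over nodes, mirrored ghost
    indices, arithmetic face averages for the axis terms and centered
    cross-derivative terms, then zero row sums via the diagonal.
    """
    nx, NY = grid.dims
    n = nx * NY
    dx_m = grid.dx * 1e-6
    sc = 1.0 / (sv * cm_area * dx_m * dx_m)
    fx, fy = grid.fiber[:, 0], grid.fiber[:, 1]
    sl, st = grid.sigma_l, grid.sigma_t
    dxx = st + (sl - st) * fx * fx
    dyy = st + (sl - st) * fy * fy
    dxy = (sl - st) * fx * fy
    A = np.zeros((n, n))

    def idx(ix, iy):
        ix = 1 if ix < 0 else (nx - 2 if ix >= nx else ix)
        iy = 1 if iy < 0 else (NY - 2 if iy >= NY else iy)
        return iy * nx + ix

    for iy in range(NY):
        for ix in range(nx):
            i = iy * nx + ix
            for dxi, dyi, comp in ((1, 0, dxx), (-1, 0, dxx),
                                   (0, 1, dyy), (0, -1, dyy)):
                j = idx(ix + dxi, iy + dyi)
                if j != i:
                    A[i, j] += 0.5 * (comp[i] + comp[j]) * sc
            if np.any(dxy != 0.0):
                c = sc * 0.25
                jE, jW = idx(ix + 1, iy), idx(ix - 1, iy)
                A[i, idx(ix + 1, iy + 1)] += c * dxy[jE]
                A[i, idx(ix + 1, iy - 1)] -= c * dxy[jE]
                A[i, idx(ix - 1, iy + 1)] -= c * dxy[jW]
                A[i, idx(ix - 1, iy - 1)] += c * dxy[jW]
                jN, jS = idx(ix, iy + 1), idx(ix, iy - 1)
                A[i, idx(ix + 1, iy + 1)] += c * dxy[jN]
                A[i, idx(ix - 1, iy + 1)] -= c * dxy[jN]
                A[i, idx(ix + 1, iy - 1)] -= c * dxy[jS]
                A[i, idx(ix - 1, iy - 1)] += c * dxy[jS]
    for i in range(n):
        A[i, i] = 0.0
        A[i, i] = -A[i].sum()
    return A



@pytest.fixture(scope="session")
def paced_traces():
    """Last-beat traces of all ten (region, condition) variants."""
    out = {}
    for region in REGIONS:
        for condition in ("control", "remodeled"):
            params = make_cell_params(region, condition)
            out[(region, condition)] = pace_cell(params, PacingProtocol())
    return out


@pytest.fixture(scope="session")
def cv_tables():
    """Per-region longitudinal conduction velocities, both conditions."""
    from atriasim.scenarios import run_cv_table

    return {cond: run_cv_table(cond).summary["cv_cm_s"]
            for cond in ("control", "remodeled")}


@pytest.fixture(scope="session")
def spiral_outcomes():
    """Cross-field S1-S2 spiral runs on the 100x100 sheet, both conditions."""
    from atriasim.scenarios import run_spiral

    return {cond: run_spiral(condition=cond)
            for cond in ("remodeled", "control")}


@pytest.fixture(scope="session")
def ring_flutter():
    from atriasim.scenarios import run_ring_flutter

    return run_ring_flutter()


@pytest.fixture(scope="session")
def blockline():
    from atriasim.scenarios import run_blockline_tachycardia

    return run_blockline_tachycardia()


@pytest.fixture(scope="session")
def plane_wave_sheet():
    """Control AWM sheet crossed by a single plane wave, with Vm stored."""
    from atriasim.monodomain import (MonodomainModel, StimulusProtocol,
                                     default_stim_amplitude, run)
    from atriasim.regions import RegionLabel, build_sheet

    grid = build_sheet(60, 60, 530.0, RegionLabel.AWM, 0.0)
    model = MonodomainModel(grid, condition="control")
    stim = np.flatnonzero(np.arange(grid.n_nodes) % 60 < 2)
    amp = default_stim_amplitude(model, stim)
    res = run(model, StimulusProtocol(((stim, 0.0, 6.0, amp),)), 420.0)
    return grid, res
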