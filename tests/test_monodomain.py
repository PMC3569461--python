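"""Monodomain solver tests: operator structure, propagation, CV."""

import numpy as np
import pytest

from atriasim.monodomain import (
    CM_AREA, DEFAULT_SV, MonodomainModel, StimulusProtocol,
    activation_map, assemble_diffusion, cable_cv, measure_cv, run,
    default_stim_amplitude,
)
from atriasim.regions import RegionLabel, build_cable, build_ring, build_sheet


from conftest import dense_fd_oracle


class TestOperator:
    @pytest.mark.parametrize("builder,angle", [
        ("cable", None), ("ring", None),
        ("sheet0", 0.0), ("sheet30", 30.0), ("sheet90", 90.0),
    ])
    def test_zero_row_sums_and_constant_nullspace(self, builder, angle):
        if builder == "cable":
            grid = build_cable(12, 530.0, RegionLabel.CT)
        elif builder == "ring":
            grid = build_ring(12, 530.0, RegionLabel.AWM)
        else:
            grid = build_sheet(7, 7, 530.0, RegionLabel.AWM, angle)
        A = assemble_diffusion(grid)
        rows = np.asarray(A.sum(axis=1)).ravel()
        np.testing.assert_allclose(rows, 0.0, atol=1e-9)
        v = np.full(grid.n_nodes, -74.25)
        np.testing.assert_allclose(A @ v, 0.0, atol=1e-6)

    @pytest.mark.parametrize("angle", [0.0, 30.0, 90.0])
    def test_matches_dense_oracle_on_5x5(self, angle):
        grid = build_sheet(5, 5, 530.0, RegionLabel.AWM, angle)
        A = assemble_diffusion(grid).toarray()
        B = dense_fd_oracle(grid, DEFAULT_SV, CM_AREA)
        np.testing.assert_allclose(A, B, rtol=1e-12, atol=1e-12)

    def test_fiber_sign_flip_leaves_operator_bitwise_identical(self):
        g1 = build_sheet(6, 6, 530.0, RegionLabel.CT, 30.0)
        g2 = build_sheet(6, 6, 530.0, RegionLabel.CT, 30.0)
        g2.fiber *= -1.0
        A1 = assemble_diffusion(g1)
        A2 = assemble_diffusion(g2)
        assert (A1 != A2).nnz == 0

    def test_0_and_90_degree_sheets_related_by_transpose(self):
        g0 = build_sheet(6, 6, 530.0, RegionLabel.CT, 0.0)
        g90 = build_sheet(6, 6, 530.0, RegionLabel.CT, 90.0)
        A0 = assemble_diffusion(g0).toarray().reshape(6, 6, 6, 6)
        A90 = assemble_diffusion(g90).toarray().reshape(6, 6, 6, 6)
        # swapping the grid axes maps one operator onto the other
        np.testing.assert_allclose(A90, A0.transpose(1, 0, 3, 2),
                                   rtol=1e-12, atol=1e-7)


class TestPropagation:
    def test_unstimulated_tissue_stays_at_rest(self):
        grid = build_cable(30, 530.0, RegionLabel.AWM)
        model = MonodomainModel(grid)
        res = run(model, StimulusProtocol(()), 500.0)
        assert np.abs(res.vm - res.vm[0]).max() < 1.0
        assert all(len(a) == 0 for a in res.activations)
        assert np.all(np.isnan(activation_map(res)))

    def test_single_wavefront_activation_increases_with_distance(self):
        grid = build_cable(80, 530.0, RegionLabel.AWM)
        model = MonodomainModel(grid)
        stim = np.arange(3)
        amp = default_stim_amplitude(model, stim)
        res = run(model, StimulusProtocol(((stim, 0.0, 6.0, amp),)), 120.0,
                  record_vm=False)
        amap = activation_map(res)
        assert np.all(np.isfinite(amap))
        assert np.all(np.diff(amap[3:]) > 0)

    def test_colliding_wavefronts_fail_cv_monotonicity_check(self):
        grid = build_cable(80, 530.0, RegionLabel.AWM)
        model = MonodomainModel(grid)
        stim_l, stim_r = np.arange(3), np.arange(77, 80)
        amp = default_stim_amplitude(model, stim_l)
        proto = StimulusProtocol(((stim_l, 0.0, 6.0, amp),
                                  (stim_r, 0.0, 6.0, amp)))
        res = run(model, proto, 120.0, record_vm=False)
        with pytest.raises(ValueError, match="monotone|collision"):
            measure_cv(res, grid)

    def test_cv_scales_as_sqrt_of_conductivity(self):
        """Quadrupling sigma doubles CV (continuum scaling, +-5%).

        Measured on the strongly coupled CT cable, where the node spacing
        is small relative to the wavefront width and the continuum square
        root law holds to a few percent.
        """
        stim = np.arange(3)
        cvs = {}
        for factor in (1.0, 4.0):
            grid = build_cable(150, 530.0, RegionLabel.CT)
            grid.sigma_l[:] *= factor
            grid.sigma_t[:] *= factor
            model = MonodomainModel(grid)
            amp = default_stim_amplitude(model, stim)
            res = run(model, StimulusProtocol(((stim, 0.0, 6.0, amp),)),
                      90.0, record_vm=False)
            cvs[factor] = measure_cv(res, grid)
        assert cvs[4.0] / cvs[1.0] == pytest.approx(2.0, rel=0.05)

    def test_cv_robust_to_halving_dt(self):
        cv_002 = cable_cv(n_nodes=100)
        cv_001 = cable_cv(n_nodes=100, dt=0.01)
        assert abs(cv_001 - cv_002) / cv_002 < 0.02

    def test_ring_wave_returns_with_same_speed(self):
        """A wave on a closed ring reenters and keeps a constant lap time."""
        from atriasim.scenarios import run_ring_flutter  # noqa: F401
        grid = build_ring(180, 530.0, RegionLabel.AWM)
        model = MonodomainModel(grid, condition="remodeled")
        open_grid = build_ring(180, 530.0, RegionLabel.AWM)
        open_grid.topology = "cable"
        a_open = assemble_diffusion(open_grid, model.sv, model.cm_area)
        stim = np.arange(1, 4)
        amp = default_stim_amplitude(model, stim)
        res1 = run(model, StimulusProtocol(((stim, 0.0, 6.0, amp),)), 100.0,
                   record_vm=False, operator=a_open)
        res2 = run(model, StimulusProtocol(()), 700.0, record_vm=False,
                   y0=res1.final_state)
        acts = res2.activations[90]
        assert len(acts) >= 3
        laps = np.diff(acts)
        assert np.std(laps) < 0.05 * np.mean(laps)


def _isochrone_axis_ratio(amap, pct):
    """Major/minor axis ratio of one isochrone band (second moments)."""
    t_iso = np.nanpercentile(amap, pct)
    iy, ix = np.nonzero(np.abs(amap - t_iso) < 1.0)
    pts = np.stack([ix, iy]).astype(float)
    pts -= pts.mean(axis=1, keepdims=True)
    ev = np.linalg.eigvalsh(pts @ pts.T / pts.shape[1])
    return float(np.sqrt(ev[-1] / ev[0]))


class TestAnisotropySpread:
    def test_isotropic_point_stimulus_gives_circular_isochrones(self):
        grid = build_sheet(51, 51, 530.0, RegionLabel.ISTHMUS, 0.0)
        model = MonodomainModel(grid)
        center = 25 * 51 + 25
        stim = np.array([center, center - 1, center + 1,
                         center - 51, center + 51])
        amp = default_stim_amplitude(model, stim)
        res = run(model, StimulusProtocol(((stim, 0.0, 6.0, amp),)), 260.0,
                  record_vm=False)
        amap = activation_map(res)
        assert _isochrone_axis_ratio(amap, 45) < 1.05

    def test_1_to_2_anisotropy_gives_sqrt2_elliptical_isochrones(self):
        """1:2 conductivity ratio spreads as a sqrt(2)-axis-ratio ellipse.

        Measured at the finest validated spacing (300 um), where the
        transverse discretization slowing is small.
        """
        grid = build_sheet(91, 65, 300.0, RegionLabel.AWM, 0.0)
        model = MonodomainModel(grid)
        center = 32 * 91 + 45
        stim = np.array([center, center - 1, center + 1,
                         center - 91, center + 91])
        amp = default_stim_amplitude(model, stim)
        res = run(model, StimulusProtocol(((stim, 0.0, 6.0, amp),)), 90.0,
                  record_vm=False)
        amap = activation_map(res)
        ratio = _isochrone_axis_ratio(amap, 30)
        assert ratio == pytest.approx(np.sqrt(2.0), rel=0.08)


class TestCvTable:
    def test_sv_calibration_anchor_is_reproduced(self):
        assert cable_cv(sv=DEFAULT_SV) == pytest.approx(69.0, rel=0.01)

    def test_cv_ordering_both_conditions(self, cv_tables):
        order = ["CT", "BB", "AWM", "PV", "ISTHMUS", "SAN"]
        for cond in ("control", "remodeled"):
            cvs = [cv_tables[cond][r] for r in order]
            assert all(np.isfinite(cvs))
            assert all(a > b for a, b in zip(cvs, cvs[1:])), (cond, cvs)

    def test_remodeling_slows_conduction_everywhere(self, cv_tables):
        for region, cv_c in cv_tables["control"].items():
            cv_r = cv_tables["remodeled"][region]
            assert cv_r < cv_c, region


def test_overlarge_dt_rejected():
    grid = build_cable(10, 530.0, RegionLabel.AWM)
    with pytest.raises(ValueError):
        MonodomainModel(grid, dt=0.05)
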