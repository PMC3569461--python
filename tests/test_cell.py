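"""Single-cell model tests: parameters, pacing, APD90, restitution."""

import numpy as np
import pytest

from atriasim import nygren as ny
from atriasim.cell import (
    CellParams, CellTrace, PacingProtocol, make_cell_params, measure_apd90,
    pace_cell, restitution_curve, step_cell, _integrate_single,
    _quiescent_state,
)
from atriasim.regions import RegionLabel


class TestParams:
    def test_awm_control_conductances(self):
        p = make_cell_params("AWM", "control")
        assert (p.g_t_max, p.g_CaL_max, p.g_Kr_max, p.g_K1_max) == \
            (7.5, 6.7, 0.5, 4.2)
        assert p.tau_fCaL_scale == 1.0
        assert p.It_act_shift == 0.0
        assert p.Cm == 50.0

    def test_remodeled_applies_conductances_and_kinetics(self):
        p = make_cell_params("AWM", "remodeled")
        # I_K1 up x2.5, I_CaL down 74%, I_t down 85% of the control values
        assert p.g_K1_max == pytest.approx(4.2 * 2.5)
        assert p.g_CaL_max == pytest.approx(1.7)
        assert p.g_t_max == pytest.approx(1.1)
        assert p.tau_fCaL_scale == pytest.approx(1.62)
        assert p.It_act_shift == 16.0
        assert p.INa_inact_shift == 1.6

    def test_ct_remodeled_ical_matches_74_percent_reduction(self):
        p = make_cell_params("CT", "remodeled")
        assert p.g_CaL_max == pytest.approx(2.7)
        assert p.g_CaL_max == pytest.approx(10.3 * 0.26, rel=0.01)

    def test_region_without_variant_rejected(self):
        with pytest.raises(ValueError):
            make_cell_params(RegionLabel.SAN, "control")
        with pytest.raises(ValueError):
            make_cell_params("AWM", "diseased")

    def test_nonpositive_conductance_rejected(self):
        with pytest.raises(ValueError):
            CellParams("AWM", "control", g_t_max=0.0, g_CaL_max=6.7,
                       g_Kr_max=0.5, g_K1_max=4.2)


class TestStepCell:
    def test_resting_cell_is_stable(self):
        p = make_cell_params("AWM", "control")
        y = np.array(_quiescent_state(p))
        t, vm, _, _ = _integrate_single(p, y, 1000.0, [])
        assert np.abs(vm - vm[0]).max() < 1.0  # < 1 mV drift over 1 s

    def test_suprathreshold_pulse_has_fast_upstroke(self):
        p = make_cell_params("AWM", "control")
        y = np.array(_quiescent_state(p))
        # full-resolution derivative via the reference stepper
        dt = 0.02
        dvdt_max = -np.inf
        for k in range(int(30.0 / dt)):
            i_stim = 1200.0 if k * dt < 6.0 else 0.0
            y_next = step_cell(y, p, i_stim, dt)
            dvdt_max = max(dvdt_max, (y_next[0] - y[0]) / (dt * 1e-3))
            y = y_next
        assert dvdt_max > 100e3  # mV/s, i.e. > 100 V/s

    def test_overlong_dt_rejected(self):
        p = make_cell_params("AWM", "control")
        y = ny.initial_state()
        with pytest.raises(ValueError):
            step_cell(y, p, 0.0, dt=10.0)

    def test_reference_and_kernel_paths_agree(self):
        """Plain-numpy reference integration matches the jitted fast path."""
        p = make_cell_params("AWM", "control")
        y_ref = np.array(_quiescent_state(p))
        # reference path: repeated step_cell over one full AP
        dt = 0.02
        n = int(400 / dt)
        vm_ref = np.empty(401)
        vm_ref[0] = y_ref[0]
        y = y_ref.copy()
        for k in range(n):
            i_stim = 1200.0 if k * dt < 6.0 else 0.0
            y = step_cell(y, p, i_stim, dt)
            if (k + 1) % 50 == 0:
                vm_ref[(k + 1) // 50] = y[0]
        t, vm_fast, _, _ = _integrate_single(p, y_ref, 400.0,
                                             [(0.0, 6.0, 1200.0)])
        # tables + per-block slow factors introduce only tiny differences
        assert np.abs(vm_fast - vm_ref).max() < 1.0
        apd_ref = measure_apd90((np.arange(401.0), vm_ref))
        apd_fast = measure_apd90((t, vm_fast))
        assert abs(apd_ref - apd_fast) < 1.0


class TestPacing:
    def test_zero_beats_rejected(self):
        with pytest.raises(ValueError):
            PacingProtocol(n_beats=0)

    def test_capture_on_every_beat_and_determinism(self):
        p = make_cell_params("AVR", "control")
        proto = PacingProtocol(bcl=500.0, n_beats=3)
        tr1 = pace_cell(p, proto)
        tr2 = pace_cell(p, proto)
        assert len(tr1.upstrokes) == 3
        np.testing.assert_array_equal(tr1.vm, tr2.vm)  # bitwise identical

    def test_remodeled_shorter_than_control_everywhere(self, paced_traces):
        for region in ("CT", "PM", "APG", "AVR", "AWM"):
            apd_c = measure_apd90(paced_traces[(region, "control")])
            apd_r = measure_apd90(paced_traces[(region, "remodeled")])
            assert apd_r < apd_c, region

    def test_regional_apd_gradient(self, paced_traces):
        """AVR is the shortest and CT the longest control variant."""
        apds = {r: measure_apd90(paced_traces[(r, "control")])
                for r in ("CT", "PM", "APG", "AVR", "AWM")}
        assert min(apds, key=apds.get) == "AVR"
        assert max(apds, key=apds.get) == "CT"

    def test_state_bounds_under_fast_remodeled_pacing(self):
        """Gates stay in [0,1] and concentrations positive at CL 130 ms."""
        p = make_cell_params("AWM", "remodeled")
        y0 = np.array(_quiescent_state(p))
        events = [(k * 130.0, 6.0, 1200.0) for k in range(15)]
        _, _, acts, yf = _integrate_single(p, y0, 2000.0, events)
        assert len(acts) >= 14  # 1:1 capture at 130 ms needs short APD
        gates = yf[ny.GATE_SLICE]
        assert np.all(gates >= 0.0) and np.all(gates <= 1.0)
        concs = yf[13:22]
        assert np.all(concs > 0.0)
        assert np.all(np.isfinite(yf))


class TestApd90:
    def test_square_pulse_apd_is_pulse_duration(self):
        t = np.arange(0.0, 400.0)
        vm = np.zeros_like(t)
        vm[(t >= 50) & (t < 250)] = 100.0
        assert measure_apd90((t, vm)) == pytest.approx(200.0, abs=1.5)

    def test_no_ap_detected_raises(self):
        t = np.arange(0.0, 300.0)
        with pytest.raises(ValueError):
            measure_apd90((t, np.full_like(t, -74.0)))


class TestRestitution:
    @pytest.fixture(scope="class")
    def curves(self):
        cis = [150.0, 250.0, 400.0, 700.0, 1000.0]
        out = {}
        for cond in ("control", "remodeled"):
            p = make_cell_params("AWM", cond)
            out[cond] = restitution_curve(p, cis)
        return out

    def test_control_monotone_nondecreasing(self, curves):
        apds = [a for _, a, ok in curves["control"] if ok]
        assert len(apds) >= 4
        assert all(b >= a - 2.0 for a, b in zip(apds, apds[1:]))

    def test_remodeled_below_control_and_flatter(self, curves):
        c = {ci: a for ci, a, ok in curves["control"] if ok}
        r = {ci: a for ci, a, ok in curves["remodeled"] if ok}
        shared = sorted(set(c) & set(r))
        assert len(shared) >= 3
        assert all(r[ci] < c[ci] for ci in shared)
        # frequency adaptation (APD span over CI) is reduced by remodeling
        assert (max(r.values()) - min(r.values())
                < max(c[ci] for ci in shared) - min(c[ci] for ci in shared))

    def test_steady_state_point_matches_standard_pacing(self, curves,
                                                        paced_traces):
        apd_1000 = dict((ci, a) for ci, a, ok in curves["control"]
                        if ok)[1000.0]
        std = measure_apd90(paced_traces[("AWM", "control")])
        assert apd_1000 == pytest.approx(std, rel=0.05)


def test_cell_params_text_round_trip(tmp_path):
    from atriasim.cell import (make_cell_params, read_cell_params,
                               write_cell_params)

    p = make_cell_params("CT", "remodeled")
    path = tmp_path / "params.txt"
    write_cell_params(p, path)
    assert read_cell_params(path) == p
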