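"""Desk-scale reproductions of the arrhythmia experiment designs.

Each scenario maps an anatomical episode onto a topology-preserving
synthetic geometry:

* ``run_cv_table`` — the conduction-velocity calibration of all regions on
  standard cables (the 2D calibration sheet's 1D equivalent).
* ``run_ring_flutter`` — macroreentry around a closed 1D ring sized so the
  circulation period is ~200 ms (the flutter cycle length); electrograms
  show single potentials, a narrow ~5 Hz dominant-frequency peak and
  organization indices near unity at every electrode.
* ``run_blockline_tachycardia`` — a high-anisotropy CT bar embedded in
  working myocardium acts as a functional block line; a premature beat
  starts a reentry circulating around the bar, and electrodes on the bar
  record double potentials (electrotonic + delayed passage) while the
  surrounding tissue shows single potentials at a uniform DF.
* ``run_focal_af`` — a continuous ectopic focus at cycle length 130 ms in
  one corner of a remodeled sheet; electrodes near the focus are regular
  (DF = 7.7 Hz, high OI) while remote tissue, unable to follow 1:1,
  shows lower DF and OI.
* ``run_spiral`` — cross-field S1-S2 induction of a spiral wave; in
  remodeled tissue (short wavelength) the spiral outlives 2 s and turns
  much faster than any reentry the longer-refractoriness control sheet
  supports.

Reentry induction uses an explicit S2-delay scan (10 ms steps) across the
vulnerable window.  All scenarios are deterministic given their
configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import analysis
from .cell import LossOfCaptureError, DivergenceError
from .egm import Electrode, egm_weights, electrode_lattice
from .monodomain import (
    DEFAULT_SV, MonodomainModel, SimulationResult, StimulusProtocol,
    assemble_diffusion, cable_cv, default_stim_amplitude, run,
)
from .regions import (
    RegionLabel, build_ring, build_sheet, build_strip_sheet,
)

__all__ = [
    "ScenarioOutput",
    "run_cv_table",
    "run_ring_flutter",
    "run_blockline_tachycardia",
    "run_focal_af",
    "run_spiral",
]

#: Regions of the conduction-velocity table, fastest to slowest.
CV_TABLE_REGIONS = (
    RegionLabel.CT, RegionLabel.BB, RegionLabel.PV,
    RegionLabel.ISTHMUS, RegionLabel.SAN, RegionLabel.AWM,
)


@dataclass
class ScenarioOutput:
    """Per-electrode analysis table plus raw traces and run metadata."""

    result: SimulationResult | None
    electrodes: list[Electrode]
    egms: np.ndarray | None          # (n_t, n_electrodes)
    table: pd.DataFrame              # electrode id, x, y, df, oi, morphology..
    summary: dict
    config: dict


def _analyze_electrodes(t, egms, electrodes, spectra: bool = True,
                        skip_ms: float = 0.0) -> pd.DataFrame:
    rows = []
    i0 = int(skip_ms)
    for k, el in enumerate(electrodes):
        phi = egms[i0:, k]
        row = {"electrode": k, "x_um": el.x, "y_um": el.y,
               "df_hz": np.nan, "oi": np.nan, "morphology": "none",
               "cl_mean_ms": np.nan, "cl_std_ms": np.nan}
        if np.abs(phi).max() > 0:
            calls = analysis.classify_morphology(phi)
            if calls:
                # majority vote over activation windows
                vals, counts = np.unique([c.cls for c in calls],
                                         return_counts=True)
                row["morphology"] = str(vals[np.argmax(counts)])
                row["double_frac"] = float(np.mean(
                    [c.cls == "double" for c in calls]))
                row["cfae_frac"] = float(np.mean(
                    [c.cls == "cfae" for c in calls]))
            env = analysis.preprocess(phi)
            try:
                cls = analysis.cycle_lengths(env)
                row["cl_mean_ms"] = float(cls.mean())
                row["cl_std_ms"] = float(cls.std())
            except ValueError:
                pass
            if spectra and len(env) >= 4000:
                sp = analysis.spectrum(env)
                if sp.df_defined:
                    row["df_hz"] = sp.df
                    row["oi"] = sp.oi
        rows.append(row)
    return pd.DataFrame(rows)


def run_cv_table(condition: str = "control", sv: float = DEFAULT_SV,
                 n_nodes: int = 150, dx: float = 530.0) -> ScenarioOutput:
    """Longitudinal conduction velocity per region on standard cables.

    A propagation failure in one region is reported as a NaN row, not a
    crash.
    """
    rows = []
    for reg in CV_TABLE_REGIONS:
        try:
            cv = cable_cv(region=reg, condition=condition,
                          n_nodes=n_nodes, dx=dx, sv=sv)
            note = ""
        except (ValueError, LossOfCaptureError, DivergenceError) as exc:
            cv, note = np.nan, f"failure: {exc}"
        rows.append({"region": reg.value, "condition": condition,
                     "cv_cm_s": cv, "note": note})
    table = pd.DataFrame(rows)
    return ScenarioOutput(
        result=None, electrodes=[], egms=None, table=table,
        summary={"condition": condition,
                 "cv_cm_s": dict(zip(table.region, table.cv_cm_s))},
        config={"scenario": "cv_table", "condition": condition, "sv": sv,
                "n_nodes": n_nodes, "dx_um": dx},
    )


def run_ring_flutter(condition: str = "remodeled",
                     target_cl_ms: float = 200.0,
                     t_total: float = 4500.0,
                     dx: float = 530.0,
                     n_electrodes: int = 8) -> ScenarioOutput:
    """Macroreentry on a ring sized for a ~200 ms circulation period.

    The ring length is CV x ``target_cl_ms``; the wave is started
    unidirectionally by integrating the first lap with the ring opened
    (cable coupling) and closing it once the front has passed 60% of the
    circumference.  Termination before 2 s is reported in the summary.
    """
    cv = cable_cv(region=RegionLabel.AWM, condition=condition, dx=dx)
    length_cm = cv * target_cl_ms * 1e-3
    n = int(round(length_cm / (dx * 1e-4)))
    grid = build_ring(n, dx, RegionLabel.AWM)
    model = MonodomainModel(grid, condition=condition)

    # open-ring operator: same grid, wrap-around couplings removed
    open_grid = build_ring(n, dx, RegionLabel.AWM)
    open_grid.topology = "cable"
    a_open = assemble_diffusion(open_grid, model.sv, model.cm_area)
    a_ring = assemble_diffusion(grid, model.sv, model.cm_area)

    stim_nodes = np.arange(1, 4)
    amp = default_stim_amplitude(model, stim_nodes)
    t_open = float(int(0.6 * length_cm / cv * 1000.0))
    res1 = run(model, StimulusProtocol(((stim_nodes, 0.0, 6.0, amp),)),
               t_open, record_vm=False, operator=a_open)

    electrodes = [Electrode(x=(i + 0.5) * length_cm * 1e4 / n_electrodes)
                  for i in range(n_electrodes)]
    W = egm_weights(grid, electrodes)
    res2 = run(model, StimulusProtocol(()), t_total - t_open,
               record_vm=False, operator=a_ring, y0=res1.final_state,
               egm_weights=W)

    last_act = max((a[-1] for a in res2.activations if len(a)), default=0.0)
    sustained = last_act >= (t_total - t_open) - 1.5 * target_cl_ms
    table = _analyze_electrodes(res2.t, res2.egm, electrodes, skip_ms=300.0)
    summary = {
        "condition": condition, "cv_cm_s": cv, "ring_length_cm": length_cm,
        "n_nodes": n, "sustained": bool(sustained),
        "last_activation_ms": float(last_act),
        "df_hz": table.df_hz.tolist(), "oi": table.oi.tolist(),
        "morphology": table.morphology.tolist(),
    }
    if not sustained:
        summary["termination_ms"] = float(last_act)
    return ScenarioOutput(res2, electrodes, res2.egm, table, summary,
                          {"scenario": "ring_flutter",
                           "condition": condition, "dx_um": dx,
                           "target_cl_ms": target_cl_ms,
                           "t_total_ms": t_total})


def _scan_s2(model, base_proto, s2_nodes, s2_amp, delays,
             check_ms, operator=None):
    """Try S2 delays (ms) until reentrant activity outlasts the window.

    The S1 state is advanced incrementally and checkpointed at each
    candidate delay, so every trial costs only the S2 observation window.
    A plain (non-reentrant) S2 beat dies within one transit plus one APD;
    activity persisting to the end of ``check_ms`` therefore signals
    reentry.  Returns the first successful delay, or None.
    """
    if operator is None:
        operator = assemble_diffusion(model.grid, model.sv, model.cm_area)
    delays = [float(d) for d in delays]
    if any(ev[1] + ev[2] > delays[0] for ev in base_proto.events):
        raise ValueError("conditioning protocol must finish before the scan")
    res = run(model, base_proto, delays[0], record_vm=False,
              operator=operator)
    state, t_cur = res.final_state, delays[0]
    for d in delays:
        if d > t_cur:
            res = run(model, StimulusProtocol(()), d - t_cur,
                      record_vm=False, operator=operator, y0=state)
            state, t_cur = res.final_state, d
        branch = StimulusProtocol(((s2_nodes, 0.0, 6.0, s2_amp),))
        try:
            res = run(model, branch, check_ms, record_vm=False,
                      operator=operator, y0=state)
        except DivergenceError:
            continue
        last = max((a[-1] for a in res.activations if len(a)), default=0.0)
        if last >= check_ms - 100.0:
            return d
    return None


def run_blockline_tachycardia(condition: str = "remodeled",
                              nx: int = 120, ny: int = 100,
                              dx: float = 530.0,
                              strip_rows: range = range(46, 54),
                              strip_col_frac: tuple = (0.10, 0.90),
                              s2_delays=range(140, 211, 10),
                              t_total: float = 1800.0) -> ScenarioOutput:
    """Reentry anchored to an embedded crista-terminalis bar.

    The CT bar (1:9 anisotropy, fibers along the bar, longer-APD CT
    cells) spans the central rows between the given column fractions,
    leaving gaps at both ends for the circuit.  An S1 plane wave from the
    bottom edge is followed by a premature S2 near the lower-right end of
    the bar; the S2 delay is scanned in 10 ms steps until a wave
    circulates around the bar.  If no delay induces reentry, the scanned
    range is reported.

    Electrodes on the bar record the block-line signature — the two limb
    passages plus electrotonic bridging — which the strict morphology
    rules read as double potentials where the passages fall in one
    activation window and as fractionated (continuous > 50 ms) activity
    otherwise; remote electrodes record single potentials.
    """
    grid = build_strip_sheet(nx, ny, dx, RegionLabel.AWM, RegionLabel.CT,
                             strip_rows)
    # restrict the bar to the central columns (gaps at both ends)
    c0, c1 = int(strip_col_frac[0] * nx), int(strip_col_frac[1] * nx)
    ix = np.arange(nx * ny) % nx
    iy = np.arange(nx * ny) // nx
    outside = np.isin(iy, list(strip_rows)) & ((ix < c0) | (ix >= c1))
    from .regions import conductivities_for, _REGION_CODE
    sl, st = conductivities_for(RegionLabel.AWM)
    grid.region[outside] = _REGION_CODE[RegionLabel.AWM]
    grid.sigma_l[outside] = sl
    grid.sigma_t[outside] = st

    model = MonodomainModel(grid, condition=condition)
    bottom = np.flatnonzero(iy < 2)
    amp = default_stim_amplitude(model, bottom)
    s1 = StimulusProtocol(((bottom, 0.0, 6.0, amp),))
    # premature beat below the right end of the bar
    s2_nodes = np.flatnonzero(
        (ix >= c1 - 12) & (ix < c1 - 2)
        & (iy >= min(strip_rows) - 12) & (iy < min(strip_rows) - 2))
    operator = assemble_diffusion(grid, model.sv, model.cm_area)
    s2_amp = default_stim_amplitude(model, s2_nodes)
    delay = _scan_s2(model, s1, s2_nodes, s2_amp, s2_delays,
                     check_ms=420.0, operator=operator)
    summary: dict = {"condition": condition, "s2_delay_ms": delay,
                     "scanned_delays_ms": list(s2_delays)}
    y_mid = (min(strip_rows) + max(strip_rows) + 1) / 2.0
    on_xs = (0.17, 0.33, 0.5, 0.67)
    electrodes = (
        [Electrode(x=f * nx * dx, y=y_mid * dx) for f in on_xs]
        + [Electrode(x=0.25 * nx * dx, y=0.85 * ny * dx),
           Electrode(x=0.75 * nx * dx, y=0.85 * ny * dx),
           Electrode(x=0.92 * nx * dx, y=0.70 * ny * dx),
           Electrode(x=0.25 * nx * dx, y=0.12 * ny * dx)]
    )
    on_strip = [True] * 4 + [False] * 4
    if delay is None:
        summary["induced"] = False
        table = pd.DataFrame()
        return ScenarioOutput(None, electrodes, None, table, summary,
                              {"scenario": "blockline", **summary})
    proto = s1 + StimulusProtocol(((s2_nodes, delay, 6.0, s2_amp),))
    W = egm_weights(grid, electrodes)
    res = run(model, proto, t_total, record_vm=False, egm_weights=W,
              operator=operator)
    table = _analyze_electrodes(res.t, res.egm, electrodes, spectra=False,
                                skip_ms=float(delay) + 30.0)
    table["on_strip"] = on_strip
    last_act = max((a[-1] for a in res.activations if len(a)), default=0.0)
    on = table[table.on_strip]
    off = table[~table.on_strip.astype(bool)]
    summary.update({
        "induced": True,
        "last_activation_ms": float(last_act),
        "sustained": bool(last_act >= t_total - 300.0),
        "on_strip_double_frac": float(on.double_frac.mean())
        if "double_frac" in on else 0.0,
        "on_strip_nonsingle_frac": float(
            (on.double_frac + on.cfae_frac).mean())
        if "double_frac" in on else 0.0,
        "off_strip_morphology": off.morphology.tolist(),
    })
    return ScenarioOutput(res, electrodes, res.egm, table, summary,
                          {"scenario": "blockline", "condition": condition,
                           "nx": nx, "ny": ny, "dx_um": dx,
                           "s2_delay_ms": delay, "t_total_ms": t_total})


def run_focal_af(condition: str = "remodeled",
                 nx: int = 150, ny: int = 150, dx: float = 530.0,
                 cl: float = 130.0, t_total: float = 4500.0,
                 electrode_spacing_um: float = 10000.0) -> ScenarioOutput:
    """Continuous ectopic focus at cycle length 130 ms in one corner.

    Near-focus electrodes should report the focus rate (DF = 7.7 Hz) with
    high OI; if the remote tissue cannot follow 1:1, its DF and OI drop.
    A uniform 1:1 capture (no fibrillatory conduction) is reported as a
    negative result together with the geometry size.
    """
    grid = build_sheet(nx, ny, dx, RegionLabel.AWM, 0.0)
    model = MonodomainModel(grid, condition=condition)
    ix = np.arange(nx * ny) % nx
    iy = np.arange(nx * ny) // nx
    focus = np.flatnonzero((ix < 6) & (iy < 6))  # ~10 mm^2 corner patch
    amp = default_stim_amplitude(model, focus)
    proto = StimulusProtocol.continuous_s2(focus, amp, t0=0.0,
                                           t_end=t_total - 10.0, cl=cl)
    electrodes = electrode_lattice(grid, electrode_spacing_um)
    W = egm_weights(grid, electrodes)
    res = run(model, proto, t_total, record_vm=False, egm_weights=W)
    table = _analyze_electrodes(res.t, res.egm, electrodes, skip_ms=300.0)
    d_cm = np.hypot(table.x_um, table.y_um) * 1e-4
    table["dist_cm"] = d_cm
    near = table[d_cm <= 1.5]
    far = table[d_cm >= d_cm.max() - 1.5]
    df_all = table.df_hz.to_numpy()
    summary = {
        "condition": condition, "cl_ms": cl, "nx": nx, "ny": ny,
        "near_df_hz": float(near.df_hz.mean()),
        "near_oi": float(near.oi.mean()),
        "far_df_hz": float(far.df_hz.mean()),
        "far_oi": float(far.oi.mean()),
        "uniform_capture": bool(np.nanmax(df_all) - np.nanmin(df_all) < 0.2),
    }
    return ScenarioOutput(res, electrodes, res.egm, table, summary,
                          {"scenario": "focal_af", "condition": condition,
                           "nx": nx, "ny": ny, "dx_um": dx, "cl_ms": cl,
                           "t_total_ms": t_total})


def run_spiral(condition: str = "remodeled", nx: int = 100, ny: int = 100,
               dx: float = 530.0, s2_delays=None,
               t_total: float = 2300.0) -> ScenarioOutput:
    """Cross-field S1-S2 spiral induction on a square sheet.

    S1 is a plane wave from the left edge; S2 depolarizes the lower-left
    quadrant, timed (10 ms scan) into the repolarization tail so its upper
    edge propagates unidirectionally and curls into a spiral.  The summary
    reports whether re-entrant activity outlasted 2 s (sustained), the
    last activation time, and the median reentry cycle length.
    """
    if s2_delays is None:
        # vulnerable window follows the S1 repolarization tail: APD plus
        # the transit time to the middle of the quadrant, for each
        # condition
        s2_delays = (range(100, 161, 10) if condition == "remodeled"
                     else range(160, 231, 10))
    grid = build_sheet(nx, ny, dx, RegionLabel.AWM, 0.0)
    model = MonodomainModel(grid, condition=condition)
    ix = np.arange(nx * ny) % nx
    iy = np.arange(nx * ny) // nx
    left = np.flatnonzero(ix < 2)
    amp = default_stim_amplitude(model, left)
    s1 = StimulusProtocol(((left, 0.0, 6.0, amp),))
    quad = np.flatnonzero((ix < nx // 2) & (iy < ny // 2))
    operator = assemble_diffusion(grid, model.sv, model.cm_area)
    s2_amp = default_stim_amplitude(model, quad)
    delay = _scan_s2(model, s1, quad, s2_amp, s2_delays,
                     check_ms=380.0, operator=operator)
    if delay is None:
        summary = {"condition": condition, "induced": False,
                   "sustained": False,
                   "scanned_delays_ms": list(s2_delays)}
        return ScenarioOutput(None, [], None, pd.DataFrame(), summary,
                              {"scenario": "spiral", "condition": condition,
                               "nx": nx, "ny": ny})
    proto = s1 + StimulusProtocol(((quad, delay, 6.0, s2_amp),))
    res = run(model, proto, t_total, record_vm=False, operator=operator)
    last_act = max((a[-1] for a in res.activations if len(a)), default=0.0)
    sustained = last_act >= 2000.0
    mean_acts = float(np.mean([len(a) for a in res.activations]))
    cls = np.concatenate([np.diff(a) for a in res.activations
                          if len(a) >= 4]) if mean_acts > 3 else np.array([])
    summary = {"condition": condition, "induced": True,
               "s2_delay_ms": delay, "last_activation_ms": float(last_act),
               "sustained": bool(sustained), "mean_activations": mean_acts,
               "median_cl_ms": float(np.median(cls)) if cls.size else None}
    return ScenarioOutput(res, [], None, pd.DataFrame(), summary,
                          {"scenario": "spiral", "condition": condition,
                           "nx": nx, "ny": ny, "dx_um": dx,
                           "s2_delay_ms": delay, "t_total_ms": t_total})
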