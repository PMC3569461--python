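"""Single-cell atrial electrophysiology: regional variants, pacing, APD90.

Five regional variants of the Nygren-type human atrial cell (crista
terminalis CT, pectinate muscles PM, appendages APG, atrioventricular rings
AVR, working myocardium AWM) differ only in the maximal conductances of
I_t, I_CaL, I_Kr and I_K1.  Chronic-AF electrical remodeling additionally
rescales the remodeled conductances and shifts two kinetic curves
(I_t activation +16 mV, I_Na inactivation +1.6 mV) and slows the fast
I_CaL inactivation by 62%.

The standard cellular protocol is a train of 10 stimuli at a basic cycle
length of 1000 ms; APD90 is read from the last beat.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass

import numpy as np

from . import nygren as ny
from . import _kernel
from .regions import RegionLabel

__all__ = [
    "CellParams",
    "PacingProtocol",
    "CellTrace",
    "make_cell_params",
    "read_cell_params",
    "write_cell_params",
    "step_cell",
    "pace_cell",
    "measure_apd90",
    "restitution_curve",
    "diastolic_threshold",
    "LossOfCaptureError",
    "DivergenceError",
]


class LossOfCaptureError(RuntimeError):
    """A pacing stimulus failed to elicit an action potential."""


class DivergenceError(RuntimeError):
    """The integrator produced a non-finite or runaway state."""


#: Maximal conductances (nS) per region and condition:
#: (g_t, g_CaL, g_Kr, g_K1).
CONDUCTANCE_TABLE: dict[str, dict[str, tuple[float, float, float, float]]] = {
    "CT":  {"control": (10.6, 10.3, 0.4, 4.2), "remodeled": (1.6, 2.7, 0.4, 10.5)},
    "PM":  {"control": (8.3, 6.2, 0.4, 4.2),  "remodeled": (1.2, 1.6, 0.4, 10.5)},
    "APG": {"control": (4.2, 6.7, 2.3, 4.2),  "remodeled": (0.6, 1.7, 2.3, 10.5)},
    "AVR": {"control": (8.3, 4.2, 2.3, 4.2),  "remodeled": (1.2, 1.1, 2.3, 10.5)},
    "AWM": {"control": (7.5, 6.7, 0.5, 4.2),  "remodeled": (1.1, 1.7, 0.5, 10.5)},
}

REMODELED_KINETICS = ny.KineticParams(
    tau_fcal_scale=1.62, it_act_shift=16.0, ina_inact_shift=1.6
)
CONTROL_KINETICS = ny.KineticParams()


@dataclass(frozen=True)
class CellParams:
    """Regional ionic parameter set (conductances in nS, Cm in pF)."""

    region: str
    condition: str
    g_t_max: float
    g_CaL_max: float
    g_Kr_max: float
    g_K1_max: float
    tau_fCaL_scale: float = 1.0
    It_act_shift: float = 0.0
    INa_inact_shift: float = 0.0
    g_sus_max: float = 2.75     # nS, sustained outward (ultrarapid) K+
    i_NaK_max: float = 70.8253  # pA, Na+/K+ pump maximum
    Cm: float = 50.0

    def __post_init__(self) -> None:
        for name in ("g_t_max", "g_CaL_max", "g_Kr_max", "g_K1_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def kinetics(self) -> ny.KineticParams:
        return ny.KineticParams(
            self.tau_fCaL_scale, self.It_act_shift, self.INa_inact_shift
        )


@dataclass(frozen=True)
class PacingProtocol:
    """Periodic single-cell pacing: n_beats rectangular pulses at ``bcl``."""

    bcl: float = 1000.0          # ms
    n_beats: int = 10
    stim_duration: float = 6.0   # ms
    stim_amplitude: float | None = None  # pA; None -> 2x diastolic threshold

    def __post_init__(self) -> None:
        if self.n_beats < 1:
            raise ValueError("n_beats must be >= 1")
        if self.bcl <= self.stim_duration:
            raise ValueError("bcl must exceed the stimulus duration")


@dataclass
class CellTrace:
    """Sampled membrane-potential trace with per-beat upstroke times."""

    t: np.ndarray          # ms
    vm: np.ndarray         # mV
    upstrokes: np.ndarray  # ms, threshold-crossing times of each AP


def write_cell_params(params: CellParams, path_or_buf) -> None:
    """Serialize a parameter set as name/value text lines."""
    from dataclasses import asdict

    lines = [f"{k} {v}" for k, v in asdict(params).items()]
    text = "\n".join(lines) + "\n"
    if hasattr(path_or_buf, "write"):
        path_or_buf.write(text)
    else:
        with open(path_or_buf, "w") as fh:
            fh.write(text)


def read_cell_params(path_or_buf) -> CellParams:
    """Read a parameter set written by :func:`write_cell_params`."""
    if hasattr(path_or_buf, "read"):
        text = path_or_buf.read()
    else:
        with open(path_or_buf) as fh:
            text = fh.read()
    kv: dict = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        k, v = line.split(None, 1)
        kv[k] = v if k in ("region", "condition") else float(v)
    return CellParams(**kv)


def make_cell_params(region: RegionLabel | str, condition: str) -> CellParams:
    """Parameter set of Table-2-style regional variants.

    ``region`` must be one of the five electrophysiological variants
    (CT, PM, APG, AVR, AWM); ``condition`` is 'control' or 'remodeled'.
    """
    name = region.value if isinstance(region, RegionLabel) else str(region)
    if name not in CONDUCTANCE_TABLE:
        raise ValueError(
            f"region {name!r} has no electrophysiological variant; "
            f"expected one of {sorted(CONDUCTANCE_TABLE)}"
        )
    if condition not in ("control", "remodeled"):
        raise ValueError("condition must be 'control' or 'remodeled'")
    g_t, g_cal, g_kr, g_k1 = CONDUCTANCE_TABLE[name][condition]
    kin = REMODELED_KINETICS if condition == "remodeled" else CONTROL_KINETICS
    return CellParams(
        region=name, condition=condition,
        g_t_max=g_t, g_CaL_max=g_cal, g_Kr_max=g_kr, g_K1_max=g_k1,
        tau_fCaL_scale=kin.tau_fcal_scale,
        It_act_shift=kin.it_act_shift,
        INa_inact_shift=kin.ina_inact_shift,
    )


def step_cell(
    state: np.ndarray, params: CellParams, i_stim: float, dt: float
) -> np.ndarray:
    """Advance one cell state one step of ``dt`` ms (reference path).

    Forward Euler for Vm and concentrations, Rush-Larsen for gates.
    Raises :class:`DivergenceError` if the step produces a non-finite state.
    """
    if dt > 0.021:
        raise ValueError("dt must be <= 0.02 ms for the stiff gate kinetics")
    if not np.all(np.isfinite(state)):
        raise DivergenceError("non-finite input state")
    dt_s = dt * 1e-3
    cur = ny.currents(state, params.g_t_max, params.g_CaL_max,
                      params.g_Kr_max, params.g_K1_max)
    dy = ny.nongate_derivatives(state, cur, i_stim)
    inf, tau = ny.gate_steady_states_and_taus(state[0], params.kinetics)
    gates = state[ny.GATE_SLICE].copy()
    out = state + dt_s * dy
    out[ny.GATE_SLICE] = inf + (gates - inf) * np.exp(-dt_s / tau)
    if not np.all(np.isfinite(out)) or abs(out[0]) > 300.0:
        raise DivergenceError(
            "state diverged after one step (dt too large or bad parameters)"
        )
    return out


def _integrate_single(
    params: CellParams,
    y0: np.ndarray,
    t_end: float,
    events: list[tuple[float, float, float]],
    dt: float = 0.02,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Fast single-cell integration; events are (start, dur, amp) in ms/pA.

    Returns (t, vm, act_times, y_final); vm sampled every 1 ms.
    """
    dt_s = dt * 1e-3
    inf, expf_full, expf_half, aux = _kernel.build_tables(params.kinetics, dt_s)
    Y = y0.reshape(1, -1).copy()
    g = lambda v: np.full(1, v)
    gt, gcal = g(params.g_t_max), g(params.g_CaL_max)
    gkr, gk1 = g(params.g_Kr_max), g(params.g_K1_max)
    gsus, gnak = g(params.g_sus_max), g(params.i_NaK_max)
    Ap = np.zeros(2, dtype=np.int32)
    Aj = np.zeros(0, dtype=np.int32)
    Ax = np.zeros(0)
    n_ms = int(round(t_end))
    nsub = int(round(1.0 / dt))
    t_out = np.arange(n_ms + 1, dtype=float)
    vm = np.empty(n_ms + 1)
    vm[0] = Y[0, 0]
    max_act = max(8, int(t_end / 100) + 4)
    act_times = np.full((1, max_act), np.nan)
    act_count = np.zeros(1, dtype=np.int32)
    v_prev = Y[:, 0].copy()
    v_scratch = np.empty(1)
    istim = np.zeros(1)
    for k in range(n_ms):
        t = float(k)
        amp = 0.0
        for start, dur, a in events:
            if start - 1e-9 <= t < start + dur - 1e-9:
                amp += a
        istim[0] = amp
        _kernel.advance_block(
            Y, gt, gcal, gkr, gk1, gsus, gnak, istim, Ap, Aj, Ax,
            dt_s, nsub, t * 1e-3,
            inf, expf_full, expf_half, aux,
            act_times, act_count, -20.0, v_prev, v_scratch,
        )
        vm[k + 1] = Y[0, 0]
        if not np.isfinite(Y).all() or abs(Y[0, 0]) > 300.0:
            raise DivergenceError(f"cell state diverged near t={k + 1} ms")
    acts = act_times[0, : act_count[0]] * 1e3  # s -> ms
    return t_out, vm, acts, Y[0]


@functools.lru_cache(maxsize=64)
def _quiescent_state(params: CellParams) -> tuple[float, ...]:
    """Resting state after 2 s of stimulus-free settling."""
    _, _, _, y = _integrate_single(params, ny.initial_state(), 2000.0, [])
    return tuple(y)


@functools.lru_cache(maxsize=64)
def diastolic_threshold(params: CellParams, duration: float = 6.0) -> float:
    """Diastolic capture threshold (pA) of a rectangular pulse, by bisection.

    Capture means Vm exceeds 0 mV within 50 ms of pulse onset, starting
    from the settled resting state.  Bisection to a 1% relative tolerance.
    """
    y0 = np.array(_quiescent_state(params))

    def captures(amp: float) -> bool:
        _, vm, _, _ = _integrate_single(
            params, y0, 50.0, [(0.0, duration, amp)]
        )
        return bool(vm.max() > 0.0)

    lo, hi = 50.0, 100.0
    while not captures(hi):
        lo, hi = hi, hi * 2.0
        if hi > 1e6:
            raise LossOfCaptureError("no capture even at 1 uA")
    while (hi - lo) / hi > 0.01:
        mid = 0.5 * (lo + hi)
        if captures(mid):
            hi = mid
        else:
            lo = mid
    return hi


def pace_cell(
    params: CellParams,
    protocol: PacingProtocol = PacingProtocol(),
    extra_ms: float | None = None,
) -> CellTrace:
    """Pace a cell with a periodic train and return the full Vm trace.

    The trace extends one full cycle beyond the last stimulus (or
    ``extra_ms``) so the final action potential repolarizes completely.
    Capture is verified on every beat; a missing upstroke raises
    :class:`LossOfCaptureError`.
    """
    amp = protocol.stim_amplitude
    if amp is None:
        amp = 2.0 * diastolic_threshold(params, protocol.stim_duration)
    y0 = np.array(_quiescent_state(params))
    tail = protocol.bcl if extra_ms is None else extra_ms
    t_end = protocol.bcl * (protocol.n_beats - 1) + tail
    events = [
        (k * protocol.bcl, protocol.stim_duration, amp)
        for k in range(protocol.n_beats)
    ]
    t, vm, acts, _ = _integrate_single(params, y0, t_end, events)
    for k in range(protocol.n_beats):
        t_stim = k * protocol.bcl
        if not np.any((acts >= t_stim) & (acts < t_stim + 50.0)):
            raise LossOfCaptureError(
                f"beat {k + 1}/{protocol.n_beats} at t={t_stim} ms "
                "did not capture"
            )
    return CellTrace(t=t, vm=vm, upstrokes=acts)


def measure_apd90(
    trace: CellTrace | tuple[np.ndarray, np.ndarray],
    which: int = -1,
) -> float:
    """APD90 (ms) of one action potential in a sampled Vm trace.

    Measured from the maximum-dV/dt point of the upstroke to recovery to
    (diastolic + 10% of AP amplitude), where the diastolic reference is the
    pre-stimulus Vm of that beat and amplitude = peak - diastolic.  The
    repolarization crossing is linearly interpolated between samples.
    """
    if isinstance(trace, CellTrace):
        t, vm = trace.t, trace.vm
    else:
        t, vm = np.asarray(trace[0], float), np.asarray(trace[1], float)
    if len(t) < 3:
        raise ValueError("trace too short")
    dvdt = np.gradient(vm, t)
    # candidate upstrokes: local dV/dt maxima above 10 V/s (= 10 mV/ms)
    cand = np.where(dvdt > 10.0)[0]
    if cand.size == 0:
        raise ValueError("no action potential detected in trace")
    groups = np.split(cand, np.where(np.diff(cand) > 5)[0] + 1)
    ups = np.array([g[np.argmax(dvdt[g])] for g in groups])
    iu = ups[which]
    # pre-stimulus diastolic reference: ~10 ms before max dV/dt
    i_dia = max(0, iu - int(round(10.0 / (t[1] - t[0]))))
    v_dia = vm[i_dia]
    nxt = ups[ups > iu]
    i_end = int(nxt[0]) if nxt.size else len(vm)
    seg = vm[iu:i_end]
    v_peak = seg.max()
    amp = v_peak - v_dia
    if amp < 40.0:
        raise ValueError("deflection too small to be an action potential")
    level = v_dia + 0.1 * amp
    ipk = iu + int(np.argmax(seg))
    below = np.where(vm[ipk:i_end] <= level)[0]
    if below.size == 0:
        raise ValueError("action potential does not repolarize to 90%")
    j = ipk + below[0]
    # linear interpolation of the crossing between samples j-1 and j
    if j > ipk and vm[j - 1] > level:
        frac = (vm[j - 1] - level) / (vm[j - 1] - vm[j])
        t_cross = t[j - 1] + frac * (t[j] - t[j - 1])
    else:
        t_cross = t[j]
    return float(t_cross - t[iu])


def last_beat_apd90(
    region: RegionLabel | str, condition: str,
    protocol: PacingProtocol = PacingProtocol(),
) -> float:
    """APD90 of the last beat of the standard 10-beat, BCL-1000-ms train."""
    params = make_cell_params(region, condition)
    trace = pace_cell(params, protocol)
    return measure_apd90(trace, which=-1)


def restitution_curve(
    params: CellParams,
    ci_list,
    n_s1: int = 10,
    bcl: float = 1000.0,
) -> list[tuple[float, float, bool]]:
    """APD90 restitution by the S1-S2 protocol.

    For each coupling interval (CI, ms, measured from the last S1 upstroke)
    a fresh run applies ``n_s1`` conditioning stimuli at ``bcl`` and a
    single premature S2; the S2 action potential's APD90 is measured.
    Returns (ci, apd90, captured) triples; non-captured CIs are flagged
    with ``captured=False`` and ``apd90=nan`` rather than raised.
    """
    amp = 2.0 * diastolic_threshold(params)
    y0 = np.array(_quiescent_state(params))
    out: list[tuple[float, float, bool]] = []
    s1_events = [(k * bcl, 6.0, amp) for k in range(n_s1)]
    t_last_s1 = (n_s1 - 1) * bcl
    # reference: upstroke of the last S1 relative to its stimulus onset
    t, vm, acts, _ = _integrate_single(params, y0, t_last_s1 + 60.0, s1_events)
    ups_offset = acts[-1] - t_last_s1
    for ci in ci_list:
        t_s2 = t_last_s1 + ups_offset + float(ci)
        t_s2 = round(t_s2)  # stimulus timing at the 1 ms event grid
        events = s1_events + [(t_s2, 6.0, amp)]
        t, vm, acts, _ = _integrate_single(
            params, y0, t_s2 + 700.0, events
        )
        s2_acts = acts[(acts >= t_s2) & (acts < t_s2 + 50.0)]
        if s2_acts.size == 0:
            out.append((float(ci), float("nan"), False))
            continue
        i0 = int(t_s2) - 20
        apd = measure_apd90((t[i0:], vm[i0:]), which=-1)
        out.append((float(ci), apd, True))
    return out
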