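"""Electrogram processing: filtering, DF/OI spectra, cycle lengths, morphology.

The processing chain mirrors clinical atrial-electrogram practice: a
40-250 Hz band-pass isolates the activation deflections, rectification and
a 20 Hz low-pass produce an activation-rate envelope, and the FFT power
spectrum of that envelope (zero-padded to a bin width of at most 0.12 Hz)
yields the dominant frequency (DF, highest peak in the 2-20 Hz analysis
band) and the organization index (OI, power within 0.75 Hz windows around
DF and its 2nd-4th harmonics over the total band power).

Morphology classification follows the standard electrogram taxonomy:
single potentials, double potentials (exactly two negative deflections in
one activation complex, the signature of conduction-block lines), and
complex fractionated electrograms (CFAE: more than two negative
deflections, or continuous activity exceeding 50 ms with no isoelectric
interval).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.signal

__all__ = [
    "FS_HZ",
    "SpectralResult",
    "DeflectionEvent",
    "MorphologyCall",
    "preprocess",
    "spectrum",
    "organization_index",
    "cycle_lengths",
    "classify_morphology",
]

FS_HZ = 1000.0          # EGM sampling rate (1 ms cadence)
DF_BAND = (2.0, 20.0)   # Hz, DF search band == OI total-power band
MAX_BIN_HZ = 0.12       # required spectral resolution
OI_WINDOW_HZ = 0.75     # width of each harmonic window


@dataclass
class SpectralResult:
    freqs: np.ndarray          # Hz
    power: np.ndarray
    df: float                  # Hz (nan if undefined)
    df_defined: bool
    oi: float | None = None

    def __post_init__(self) -> None:
        if self.df_defined and not (DF_BAND[0] <= self.df <= DF_BAND[1]):
            raise ValueError("DF outside the analysis band")


@dataclass(frozen=True)
class DeflectionEvent:
    t: float        # ms
    polarity: str   # {"positive", "negative"}
    amplitude: float  # fraction of the trace's max |deflection|


@dataclass
class MorphologyCall:
    cls: str                     # {"single", "double", "cfae"}
    t_center: float              # ms, center of the activation window
    deflections: list[DeflectionEvent] = field(default_factory=list)
    continuous_ms: float = 0.0   # longest span without isoelectric line

    @property
    def n_negative(self) -> int:
        return sum(1 for d in self.deflections if d.polarity == "negative")


def _sos(low, high=None, order=4):
    if high is None:
        return scipy.signal.butter(order, low / (FS_HZ / 2), "low", output="sos")
    return scipy.signal.butter(
        order, [low / (FS_HZ / 2), high / (FS_HZ / 2)], "band", output="sos"
    )


_SOS_BAND = _sos(40.0, 250.0)
_SOS_LOW = _sos(20.0)


def preprocess(phi: np.ndarray) -> np.ndarray:
    """40-250 Hz band-pass -> rectify -> 20 Hz low-pass, all zero-phase.

    4th-order Butterworth filters applied forward-backward (zero phase so
    activation timing survives for cycle-length extraction).  Requires at
    least 500 ms of signal at 1 kHz for the filter transients.
    """
    phi = np.asarray(phi, dtype=float)
    if phi.ndim != 1:
        raise ValueError("expected a single-channel trace")
    if len(phi) < 500:
        raise ValueError("trace shorter than the 500 ms filter warm-up")
    bp = scipy.signal.sosfiltfilt(_SOS_BAND, phi)
    return scipy.signal.sosfiltfilt(_SOS_LOW, np.abs(bp))


def spectrum(env: np.ndarray, resolution: float = MAX_BIN_HZ) -> SpectralResult:
    """Zero-padded FFT power spectrum of a processed envelope.

    The record must be at least 4 s long; zero-padding (next power of two
    reaching a bin width <= ``resolution``) supplies the stated frequency
    resolution; no taper window is applied.  DF is the frequency of the
    global power maximum within the 2-20 Hz band; exact ties break toward
    the lower frequency.  All-zero input is flagged (``df_defined=False``)
    rather than returned as NaN power.
    """
    env = np.asarray(env, dtype=float)
    if len(env) < 4000:
        raise ValueError("need >= 4 s of signal for spectral analysis")
    nfft = 1
    while FS_HZ / nfft > resolution or nfft < len(env):
        nfft *= 2
    sig = env - env.mean()
    spec = np.abs(np.fft.rfft(sig, nfft)) ** 2
    freqs = np.fft.rfftfreq(nfft, d=1.0 / FS_HZ)
    band = (freqs >= DF_BAND[0]) & (freqs <= DF_BAND[1])
    if not np.any(spec[band] > 0.0):
        return SpectralResult(freqs, spec, float("nan"), False)
    bi = np.flatnonzero(band)
    df = float(freqs[bi[int(np.argmax(spec[bi]))]])  # argmax -> lowest tie
    res = SpectralResult(freqs, spec, df, True)
    res.oi = organization_index(res)
    return res


def organization_index(spec: SpectralResult) -> float:
    """OI: power near DF and harmonics 2f..4f over total band power.

    Each harmonic window is ``OI_WINDOW_HZ`` wide, centered on k*DF;
    overlapping windows are merged so no power is double-counted.  The
    total is the power in the 2-20 Hz analysis band.  Result in [0, 1].
    """
    if not spec.df_defined:
        raise ValueError("OI undefined: no dominant frequency")
    freqs, power = spec.freqs, spec.power
    band = (freqs >= DF_BAND[0]) & (freqs <= DF_BAND[1])
    total = power[band].sum()
    if total <= 0:
        return 0.0
    half = OI_WINDOW_HZ / 2.0
    inwin = np.zeros_like(freqs, dtype=bool)
    for k in (1, 2, 3, 4):
        f0 = k * spec.df
        inwin |= (freqs >= f0 - half) & (freqs <= f0 + half)
    return float(power[inwin & band].sum() / total)


def cycle_lengths(env: np.ndarray, height_frac: float = 0.3,
                  min_distance_ms: float = 60.0) -> np.ndarray:
    """Cycle lengths (ms) between successive activations of an envelope.

    Activations are threshold peaks of the processed envelope (height at
    least ``height_frac`` of the envelope maximum, separated by at least
    ``min_distance_ms``).  Raises if fewer than two activations are found.
    """
    env = np.asarray(env, dtype=float)
    if env.max() <= 0:
        raise ValueError("flat envelope: no activations")
    peaks, _ = scipy.signal.find_peaks(
        env, height=height_frac * env.max(),
        distance=int(min_distance_ms * FS_HZ / 1000.0),
    )
    if len(peaks) < 2:
        raise ValueError("fewer than two activations detected")
    return np.diff(peaks) * (1000.0 / FS_HZ)


def _lobes(seg: np.ndarray, thr: float):
    """Signed deflections: prominent peaks of each polarity above thr.

    A deflection is a local extremum exceeding ``thr`` in amplitude with a
    prominence of at least half the threshold, so two downward strokes
    separated by a partial (not necessarily zero-crossing) recovery count
    as two negative deflections — the waveform reading used for
    double-potential and fractionation criteria.
    """
    out = []
    for sign, pol in ((1.0, "positive"), (-1.0, "negative")):
        peaks, props = scipy.signal.find_peaks(
            sign * seg, height=thr, prominence=0.5 * thr)
        for p, h in zip(peaks, props["peak_heights"]):
            out.append((int(p), pol, float(h)))
    # endpoints can carry a clipped extremum that find_peaks misses
    out.sort()
    return out


def classify_morphology(
    phi: np.ndarray,
    deflection_frac: float = 0.10,
    iso_frac: float = 0.05,
    iso_min_ms: float = 10.0,
    window_ms: float = 90.0,
    merge_ms: float = 50.0,
    continuous_ms: float = 50.0,
) -> list[MorphologyCall]:
    """Classify each activation complex of a raw (unrectified) electrogram.

    Activation windows (``window_ms`` wide) are centered on peaks of the
    processed envelope; complexes closer than ``merge_ms`` merge into one
    window (this is what lets the >50 ms continuous-activity CFAE rule
    fire).  Within a window, deflections are signed lobes exceeding
    ``deflection_frac`` of the trace's maximum absolute deflection, and the
    isoelectric line is |phi| below ``iso_frac`` of that maximum for at
    least ``iso_min_ms``.

    Classes: ``cfae`` if more than two negative deflections or continuous
    activity exceeds ``continuous_ms``; ``double`` for exactly two negative
    deflections; ``single`` otherwise.  A flat trace returns the empty
    list (the "no activity" sentinel).
    """
    phi = np.asarray(phi, dtype=float)
    phi = phi - np.median(phi)
    amax = np.abs(phi).max()
    if amax <= 0 or not np.isfinite(amax):
        return []
    env = preprocess(phi)
    if env.max() <= 0:
        return []
    peaks, _ = scipy.signal.find_peaks(env, height=0.15 * env.max(),
                                       distance=20)
    if len(peaks) == 0:
        return []
    # merge close peaks into windows
    groups: list[list[int]] = [[int(peaks[0])]]
    for p in peaks[1:]:
        if p - groups[-1][-1] <= merge_ms:
            groups[-1].append(int(p))
        else:
            groups.append([int(p)])
    thr = deflection_frac * amax
    iso_thr = iso_frac * amax
    calls = []
    half = window_ms / 2.0
    for g in groups:
        lo = max(0, int(g[0] - half))
        hi = min(len(phi), int(g[-1] + half))
        seg = phi[lo:hi]
        defl = [
            DeflectionEvent(t=float(lo + tp), polarity=pol,
                            amplitude=float(a / amax))
            for tp, pol, a in _lobes(seg, thr)
        ]
        # longest continuous span of supra-isoelectric activity
        active = np.abs(seg) >= iso_thr
        best = run = 0
        gap = 0
        iso_min = int(iso_min_ms)
        for a in active:
            if a:
                run += gap if gap < iso_min else 0
                gap = 0
                run += 1
                best = max(best, run)
            else:
                gap += 1
                if gap >= iso_min:
                    run = 0
        n_neg = sum(1 for d in defl if d.polarity == "negative")
        if n_neg > 2 or best > continuous_ms:
            cls = "cfae"
        elif n_neg == 2:
            cls = "double"
        else:
            cls = "single"
        calls.append(MorphologyCall(
            cls=cls, t_center=float(np.mean(g)), deflections=defl,
            continuous_ms=float(best),
        ))
    return calls
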