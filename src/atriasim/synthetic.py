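"""Synthetic electrogram generator for exercising the analysis chain.

Produces periodic trains of unipolar-EGM-like complexes with controllable
cycle length, morphology class (single / double / CFAE), timing jitter and
additive broadband noise, sampled at 1 kHz.  These emulate the signal
classes the analysis chain must separate without requiring a tissue
simulation: a biphasic RS complex for ordinary activations, a second
negative deflection 40 ms later for double potentials (block lines), and a
burst of alternating low-amplitude deflections spanning >50 ms with no
isoelectric gap for fractionated electrograms.
"""

from __future__ import annotations

import numpy as np

from .analysis import FS_HZ

__all__ = ["biphasic_complex", "make_egm"]


def biphasic_complex(width_ms: float = 14.0, rs_ratio: float = 1.0,
                     fs: float = FS_HZ) -> np.ndarray:
    """Biphasic (positive-then-negative) activation complex template.

    Derivative-of-Gaussian shape; ``rs_ratio`` scales the positive (R)
    lobe relative to the negative (S) lobe.
    """
    sigma = width_ms / 6.0
    t = np.arange(-3 * sigma, 3 * sigma + 1e-9, 1000.0 / fs)
    w = -t * np.exp(-(t ** 2) / (2 * sigma ** 2))
    w = w / np.abs(w).max()
    w[w > 0] *= rs_ratio
    return w


def _negative_complex(width_ms: float = 12.0, fs: float = FS_HZ) -> np.ndarray:
    sigma = width_ms / 6.0
    t = np.arange(-3 * sigma, 3 * sigma + 1e-9, 1000.0 / fs)
    return -np.exp(-(t ** 2) / (2 * sigma ** 2))


def _cfae_complex(n_deflections: int = 5, spacing_ms: float = 14.0,
                  fs: float = FS_HZ) -> np.ndarray:
    """Alternating low-amplitude deflections with no isoelectric gap."""
    parts = []
    for k in range(n_deflections):
        lobe = _negative_complex(width_ms=spacing_ms * 1.6, fs=fs)
        parts.append(lobe if k % 2 == 0 else -lobe)
    step = int(spacing_ms * fs / 1000.0)
    total = step * (n_deflections - 1) + len(parts[0])
    out = np.zeros(total)
    for k, p in enumerate(parts):
        out[k * step: k * step + len(p)] += 0.4 * p
    return out


def make_egm(
    cl: float = 200.0,
    duration: float = 8000.0,
    morphology: str = "single",
    jitter: float = 0.0,
    noise: float = 0.0,
    seed: int | None = None,
    fs: float = FS_HZ,
) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic EGM train: returns (t_ms, phi).

    Parameters
    ----------
    cl : mean cycle length, ms
    duration : record length, ms
    morphology : {"single", "double", "cfae"} complex template
    jitter : standard deviation (ms) of Gaussian activation-time jitter
    noise : RMS of additive white noise, as a fraction of unit amplitude
    seed : RNG seed (jitter and noise are the only randomness)
    """
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs / 1000.0))
    phi = np.zeros(n)
    if morphology == "single":
        template = biphasic_complex(fs=fs)
    elif morphology == "double":
        main = biphasic_complex(fs=fs)
        second = _negative_complex(fs=fs) * 0.7
        off = int(40.0 * fs / 1000.0)
        template = np.zeros(off + len(second))
        template[: len(main)] += main
        template[off: off + len(second)] += second
    elif morphology == "cfae":
        template = _cfae_complex(fs=fs)
    else:
        raise ValueError(f"unknown morphology {morphology!r}")

    t_act = 50.0
    while t_act < duration - 100.0:
        t = t_act + (rng.normal(0.0, jitter) if jitter > 0 else 0.0)
        i0 = int(round(t * fs / 1000.0))
        if 0 <= i0 < n - len(template):
            phi[i0: i0 + len(template)] += template
        t_act += cl
    if noise > 0:
        phi = phi + rng.normal(0.0, noise, size=n)
    t_ms = np.arange(n) * (1000.0 / fs)
    return t_ms, phi
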