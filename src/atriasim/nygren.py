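"""Nygren-type human atrial ionic cell model (reference implementation).

This module holds the full equation set of the Nygren et al. adult human
atrial cell model in its native units (mV, pA, nS, mM, nL, seconds), as a
plain-numpy right-hand side that vectorizes over nodes.  Regional
electrophysiological variants and chronic-AF remodeling enter purely as
parameter overrides:

* maximal conductances of I_t, I_CaL, I_Kr and I_K1 (per region/condition),
* a multiplicative scale on the fast I_CaL inactivation time constant,
* voltage shifts of the I_t steady-state activation curve and of the I_Na
  steady-state inactivation curve.

The numpy path here is the readable reference; :mod:`atriasim._kernel`
implements the same equations with tabulated gate kinetics for speed, and
the two are cross-checked in the test suite.

State vector layout (29 variables) is given by :data:`STATE_NAMES`; gating
variables occupy the contiguous slice ``GATE_SLICE`` and are advanced with
Rush-Larsen exponential updates, everything else with forward Euler.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "STATE_NAMES",
    "N_STATE",
    "GATE_SLICE",
    "KineticParams",
    "initial_state",
    "gate_steady_states_and_taus",
    "currents",
    "nongate_derivatives",
]

# --- physical constants (native model units) -------------------------------
R = 8314.0        # mJ mol^-1 K^-1
T = 306.15        # K
F = 96487.0       # C mol^-1
RTF = R * T / F   # mV

CM_NF = 0.05      # membrane capacitance, nF (50 pF)

# cell compartment volumes, nL
VOL_I = 0.005884
VOL_C = 0.136 * VOL_I
VOL_D = 0.02 * VOL_I
VOL_REL = 0.0000441
VOL_UP = 0.0003969

# bulk (bath) concentrations, mM, and cleft diffusion time constants, s
NA_B, K_B, CA_B = 130.0, 5.4, 1.8
TAU_NA, TAU_K, TAU_CA = 14.3, 10.0, 24.7

# fixed current parameters (not regionally varied)
P_NA = 0.0016          # nL s^-1
G_SUS = 2.75           # nS
G_KS = 1.0             # nS
G_B_NA = 0.060599      # nS
G_B_CA = 0.078681      # nS
I_NAK_MAX = 70.8253    # pA
K_NAK_K = 1.0          # mM
K_NAK_NA = 11.0        # mM
I_CAP_MAX = 4.0        # pA
K_CAP = 0.0002         # mM
K_NACA = 0.0374842     # pA mM^-4
GAMMA_NACA = 0.45
D_NACA = 0.0003
PHI_NA_EN = -1.68      # pA, electroneutral Na influx
E_CA_APP = 60.0        # mV
K_CA = 0.025           # mM

# SR / buffering parameters
I_UP_MAX = 2800.0      # pA
K_CYCA = 0.0003        # mM
K_SRCA = 0.5           # mM
K_XCS = 0.4
TAU_TR = 0.01          # s
ALPHA_REL = 200000.0   # pA mM^-1
K_REL_I = 0.0003       # mM
K_REL_D = 0.003        # mM
R_RECOV = 0.815        # s^-1
MG_I = 2.5             # mM

STATE_NAMES = (
    "V",
    "m", "h1", "h2", "d_L", "f_L1", "f_L2",
    "r", "s", "r_sus", "s_sus", "n", "p_a",
    "Na_c", "K_c", "Ca_c",
    "Na_i", "K_i", "Ca_i", "Ca_d",
    "Ca_up", "Ca_rel", "O_Calse",
    "O_C", "O_TC", "O_TMgC", "O_TMgMg",
    "F1", "F2",
)
N_STATE = len(STATE_NAMES)
IDX = {name: i for i, name in enumerate(STATE_NAMES)}
GATE_SLICE = slice(1, 13)   # m .. p_a
N_GATES = 12


@dataclass(frozen=True)
class KineticParams:
    """Condition-level kinetic modifiers (identical across regions).

    ``tau_fcal_scale`` multiplies the fast I_CaL inactivation time constant;
    the shifts (mV) move the I_t steady-state activation curve and the I_Na
    steady-state inactivation curve along the voltage axis.  Control is
    (1, 0, 0); chronic-AF remodeling is (1.62, +16, +1.6).
    """

    tau_fcal_scale: float = 1.0
    it_act_shift: float = 0.0
    ina_inact_shift: float = 0.0


#: Resting-state initial conditions of the original model formulation.
_Y0 = {
    "V": -74.2525,
    "m": 3.2017e-3, "h1": 0.8814, "h2": 0.8742,
    "d_L": 1.3005e-5, "f_L1": 0.9986, "f_L2": 0.9986,
    "r": 1.0678e-3, "s": 0.9490,
    "r_sus": 1.5949e-4, "s_sus": 0.9912,
    "n": 4.8357e-3, "p_a": 0.0001,
    "Na_c": 130.011, "K_c": 5.3581, "Ca_c": 1.8147,
    "Na_i": 8.5547, "K_i": 129.435, "Ca_i": 6.729e-5, "Ca_d": 7.2495e-5,
    "Ca_up": 0.6646, "Ca_rel": 0.6465, "O_Calse": 0.4369,
    "O_C": 0.0275, "O_TC": 0.0133, "O_TMgC": 0.1961, "O_TMgMg": 0.7094,
    "F1": 0.4284, "F2": 0.0028,
}


def initial_state(n: int | None = None) -> np.ndarray:
    """Resting initial state; shape (29,) or (n, 29)."""
    y = np.array([_Y0[name] for name in STATE_NAMES])
    if n is None:
        return y
    return np.tile(y, (n, 1))


def gate_steady_states_and_taus(v: np.ndarray, kin: KineticParams):
    """Steady states and time constants (s) for the 12 gates at voltage v.

    Returns two arrays of shape (12,) + v.shape ordered as in STATE_NAMES
    [m, h1, h2, d_L, f_L1, f_L2, r, s, r_sus, s_sus, n, p_a].
    """
    v = np.asarray(v, dtype=float)
    m_inf = 1.0 / (1.0 + np.exp(-(v + 27.12) / 8.21))
    tau_m = 4.2e-5 * np.exp(-(((v + 25.57) / 28.8) ** 2)) + 2.4e-5

    vh = v - kin.ina_inact_shift
    h_inf = 1.0 / (1.0 + np.exp((vh + 63.6) / 5.3))
    tau_h1 = 0.03 / (1.0 + np.exp((v + 35.1) / 3.2)) + 0.0003
    tau_h2 = 0.12 / (1.0 + np.exp((v + 35.1) / 3.2)) + 0.003

    dl_inf = 1.0 / (1.0 + np.exp(-(v + 9.0) / 5.8))
    tau_dl = 0.0027 * np.exp(-(((v + 35.0) / 30.0) ** 2)) + 0.002
    fl_inf = 1.0 / (1.0 + np.exp((v + 27.4) / 7.1))
    tau_fl1 = kin.tau_fcal_scale * (
        0.161 * np.exp(-(((v + 40.0) / 14.4) ** 2)) + 0.010
    )
    tau_fl2 = 1.3323 * np.exp(-(((v + 40.0) / 14.2) ** 2)) + 0.0626

    vr = v - kin.it_act_shift
    r_inf = 1.0 / (1.0 + np.exp(-(vr - 1.0) / 11.0))
    tau_r = 0.0035 * np.exp(-((v / 30.0) ** 2)) + 0.0015
    s_inf = 1.0 / (1.0 + np.exp((v + 40.5) / 11.5))
    tau_s = 0.4812 * np.exp(-(((v + 52.45) / 14.97) ** 2)) + 0.01414

    rsus_inf = 1.0 / (1.0 + np.exp(-(v + 4.3) / 8.0))
    tau_rsus = 0.009 / (1.0 + np.exp((v + 5.0) / 12.0)) + 0.0005
    ssus_inf = 0.4 / (1.0 + np.exp((v + 20.0) / 10.0)) + 0.6
    tau_ssus = 0.047 / (1.0 + np.exp((v + 60.0) / 10.0)) + 0.3

    n_inf = 1.0 / (1.0 + np.exp(-(v - 19.9) / 12.7))
    tau_n = 0.7 + 0.4 * np.exp(-(((v - 20.0) / 20.0) ** 2))

    pa_inf = 1.0 / (1.0 + np.exp(-(v + 15.0) / 6.0))
    tau_pa = 0.03118 + 0.21718 * np.exp(-(((v + 20.1376) / 22.1996) ** 2))

    inf = np.stack([m_inf, h_inf, h_inf, dl_inf, fl_inf, fl_inf,
                    r_inf, s_inf, rsus_inf, ssus_inf, n_inf, pa_inf])
    tau = np.stack([tau_m, tau_h1, tau_h2, tau_dl, tau_fl1, tau_fl2,
                    tau_r, tau_s, tau_rsus, tau_ssus, tau_n, tau_pa])
    return inf, tau


def currents(y: np.ndarray, g_t, g_cal, g_kr, g_k1):
    """All membrane currents (pA) for state array y of shape (..., 29).

    Conductances are in nS and broadcast against the leading axes of y.
    Returns a dict of current arrays plus the reversal potentials.
    """
    V = y[..., IDX["V"]]
    m, h1, h2 = y[..., 1], y[..., 2], y[..., 3]
    d_L, f_L1, f_L2 = y[..., 4], y[..., 5], y[..., 6]
    r, s = y[..., 7], y[..., 8]
    r_sus, s_sus = y[..., 9], y[..., 10]
    n, p_a = y[..., 11], y[..., 12]
    Na_c, K_c, Ca_c = y[..., 13], y[..., 14], y[..., 15]
    Na_i, K_i, Ca_i, Ca_d = y[..., 16], y[..., 17], y[..., 18], y[..., 19]

    e_na = RTF * np.log(Na_c / Na_i)
    e_k = RTF * np.log(K_c / K_i)
    e_ca = 0.5 * RTF * np.log(Ca_c / Ca_i)

    expv = np.exp(V / RTF)
    # GHK-type driving term, finite at V = 0
    with np.errstate(invalid="ignore"):
        vfac = np.where(np.abs(V) < 1e-9, RTF, V / (expv - 1.0))
    # equals P_Na m^3 h Na_c V F^2/(RT) (e^((V-E_Na)F/RT)-1)/(e^(VF/RT)-1)
    i_na = (
        P_NA * m ** 3 * (0.9 * h1 + 0.1 * h2) * Na_c * F / RTF
        * vfac * (expv * Na_i / Na_c - 1.0)
    )

    f_ca = Ca_d / (Ca_d + K_CA)
    i_cal = g_cal * d_L * (f_ca * f_L1 + (1.0 - f_ca) * f_L2) * (V - E_CA_APP)

    i_t = g_t * r * s * (V - e_k)
    i_sus = G_SUS * r_sus * s_sus * (V - e_k)
    i_ks = G_KS * n * (V - e_k)
    p_i = 1.0 / (1.0 + np.exp((V + 55.0) / 24.0))
    i_kr = g_kr * p_a * p_i * (V - e_k)
    i_k1 = (
        g_k1 * np.power(K_c, 0.4457) * (V - e_k)
        / (1.0 + np.exp(1.5 * (V - e_k + 3.6) / RTF))
    )
    i_b_na = G_B_NA * (V - e_na)
    i_b_ca = G_B_CA * (V - e_ca)
    i_nak = (
        I_NAK_MAX * K_c / (K_c + K_NAK_K)
        * Na_i ** 1.5 / (Na_i ** 1.5 + K_NAK_NA ** 1.5)
        * (V + 150.0) / (V + 200.0)
    )
    i_cap = I_CAP_MAX * Ca_i / (Ca_i + K_CAP)
    i_naca = (
        K_NACA
        * (Na_i ** 3 * Ca_c * np.exp(GAMMA_NACA * V / RTF)
           - Na_c ** 3 * Ca_i * np.exp((GAMMA_NACA - 1.0) * V / RTF))
        / (1.0 + D_NACA * (Na_c ** 3 * Ca_i + Na_i ** 3 * Ca_c))
    )
    total = (i_na + i_cal + i_t + i_sus + i_k1 + i_kr + i_ks
             + i_b_na + i_b_ca + i_nak + i_cap + i_naca)
    return {
        "i_na": i_na, "i_cal": i_cal, "i_t": i_t, "i_sus": i_sus,
        "i_k1": i_k1, "i_kr": i_kr, "i_ks": i_ks, "i_b_na": i_b_na,
        "i_b_ca": i_b_ca, "i_nak": i_nak, "i_cap": i_cap, "i_naca": i_naca,
        "i_total": total, "e_na": e_na, "e_k": e_k, "e_ca": e_ca,
    }


def nongate_derivatives(y: np.ndarray, cur: dict, i_stim=0.0) -> np.ndarray:
    """Time derivatives (per second) of the 17 non-gate states.

    ``i_stim`` is the depolarizing stimulus current in pA (positive
    depolarizes).  Returns an array shaped like y with gate entries zero.
    """
    dy = np.zeros_like(y)
    Na_c, K_c, Ca_c = y[..., 13], y[..., 14], y[..., 15]
    Na_i, K_i, Ca_i, Ca_d = y[..., 16], y[..., 17], y[..., 18], y[..., 19]
    Ca_up, Ca_rel, O_Calse = y[..., 20], y[..., 21], y[..., 22]
    O_C, O_TC, O_TMgC, O_TMgMg = y[..., 23], y[..., 24], y[..., 25], y[..., 26]
    F1, F2 = y[..., 27], y[..., 28]

    dy[..., 0] = (-(cur["i_total"]) + i_stim) / CM_NF  # pA / nF = mV/s

    i_na_flux = (cur["i_na"] + cur["i_b_na"] + 3.0 * cur["i_nak"]
                 + 3.0 * cur["i_naca"] + PHI_NA_EN)
    i_k_flux = (cur["i_t"] + cur["i_sus"] + cur["i_k1"] + cur["i_ks"]
                + cur["i_kr"] - 2.0 * cur["i_nak"])
    i_ca_flux = cur["i_cal"] + cur["i_b_ca"] + cur["i_cap"] - 2.0 * cur["i_naca"]

    dy[..., 13] = (NA_B - Na_c) / TAU_NA + i_na_flux / (VOL_C * F)
    dy[..., 14] = (K_B - K_c) / TAU_K + i_k_flux / (VOL_C * F)
    dy[..., 15] = (CA_B - Ca_c) / TAU_CA + i_ca_flux / (2.0 * VOL_C * F)

    dy[..., 16] = -i_na_flux / (VOL_I * F)
    dy[..., 17] = -i_k_flux / (VOL_I * F)

    i_di = (Ca_d - Ca_i) * 2.0 * F * VOL_D / 0.010
    dy[..., 19] = -(cur["i_cal"] + i_di) / (2.0 * VOL_D * F)

    i_up = (
        I_UP_MAX * (Ca_i / K_CYCA - K_XCS ** 2 * Ca_up / K_SRCA)
        / ((Ca_i + K_CYCA) / K_CYCA + K_XCS * (Ca_up + K_SRCA) / K_SRCA)
    )
    i_tr = (Ca_up - Ca_rel) * 2.0 * F * VOL_REL / TAU_TR
    i_rel = ALPHA_REL * (F2 / (F2 + 0.25)) ** 2 * (Ca_rel - Ca_i)

    d_oc = 200000.0 * Ca_i * (1.0 - O_C) - 476.0 * O_C
    d_otc = 78400.0 * Ca_i * (1.0 - O_TC) - 392.0 * O_TC
    d_otmgc = 200000.0 * Ca_i * (1.0 - O_TMgC - O_TMgMg) - 6.6 * O_TMgC
    d_otmgmg = 2000.0 * MG_I * (1.0 - O_TMgC - O_TMgMg) - 666.0 * O_TMgMg
    d_ocalse = 480.0 * Ca_rel * (1.0 - O_Calse) - 400.0 * O_Calse

    dy[..., 18] = (
        -(-i_di + cur["i_b_ca"] + cur["i_cap"] - 2.0 * cur["i_naca"]
          + i_up - i_rel) / (2.0 * VOL_I * F)
        - (0.045 * d_oc + 0.08 * d_otc + 0.16 * d_otmgc)
    )
    dy[..., 20] = (i_up - i_tr) / (2.0 * VOL_UP * F)
    dy[..., 21] = (i_tr - i_rel) / (2.0 * VOL_REL * F) - 31.0 * d_ocalse
    dy[..., 22] = d_ocalse
    dy[..., 23] = d_oc
    dy[..., 24] = d_otc
    dy[..., 25] = d_otmgc
    dy[..., 26] = d_otmgmg

    ract = 203.8 * ((Ca_i / (Ca_i + K_REL_I)) ** 4 + (Ca_d / (Ca_d + K_REL_D)) ** 4)
    rinact = 33.96 + 339.6 * (Ca_i / (Ca_i + K_REL_I)) ** 4
    dy[..., 27] = R_RECOV * (1.0 - F1 - F2) - ract * F1
    dy[..., 28] = ract * F1 - rinact * F2
    return dy
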