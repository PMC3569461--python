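# Methods

## Cellular model

The cell model is a full implementation of the Nygren-type adult human
atrial myocyte: 29 state variables comprising V_m, twelve Hodgkin–Huxley
gates (I_Na m/h1/h2, I_CaL d_L/f_L1/f_L2 with Ca-dependent blending of the
two inactivation gates, I_t r/s, I_sus r_sus/s_sus, I_Ks n, I_Kr p_a),
cleft-space and intracellular Na+/K+/Ca2+ concentrations, sarcoplasmic-
reticulum uptake/release compartments with a two-state release channel,
and four ODE-based cytosolic Ca2+ buffers. Native units: mV, pA, nS, mM,
nL, seconds; C_m = 50 pF; T = 306.15 K. The published resting state is
the initial condition; cells are settled for 2 s without stimulus before
any protocol.

Regional heterogeneity enters purely as maximal-conductance overrides
(nS):

| variant | g_t | g_CaL | g_Kr | g_K1 |
|---------|-----|-------|------|------|
| CT      | 10.6| 10.3  | 0.4  | 4.2  |
| PM      | 8.3 | 6.2   | 0.4  | 4.2  |
| APG     | 4.2 | 6.7   | 2.3  | 4.2  |
| AVR     | 8.3 | 4.2   | 2.3  | 4.2  |
| AWM     | 7.5 | 6.7   | 0.5  | 4.2  |

Chronic-AF remodeling multiplies g_K1 by 2.5, cuts g_CaL by 74% and g_t
by 85%, scales the fast I_CaL inactivation time constant by 1.62, and
shifts the I_t steady-state activation by +16 mV and the I_Na steady-state
inactivation by +1.6 mV (steady-state curves only; the time constants are
left at their published voltage dependence). Structures without their own
variant (Bachmann's bundle, fossa-ovalis rim, pulmonary veins, isthmus,
SAN) use the AWM variant by default, overridable per model. The sustained
outward conductance (2.75 nS) and Na+/K+-pump maximum (70.8253 pA) are
exposed as ordinary parameters at their published defaults.

**Single-cell stimulation.** Rectangular 6 ms pulses. The published
tissue stimulus (30 µA over ~10 mm²) does not translate to an isolated
cell, so the single-cell amplitude defaults to twice the diastolic
capture threshold, found once per variant by bisection to 1%
(`diastolic_threshold`). APD90 is measured from the maximum-upstroke-
velocity point to recovery to (pre-stimulus diastolic + 10% of the AP
amplitude), with the repolarization crossing linearly interpolated
between 1 ms samples; the diastolic reference is per-beat, which keeps
the definition unambiguous under incomplete repolarization at short
coupling intervals.

**Restitution.** S1–S2: ten conditioning beats at BCL 1000 ms, one
premature S2 per run at each coupling interval (measured from the last S1
upstroke); non-captured intervals are flagged, not raised.

## Tissue model

Monodomain equation with conductivity tensor
D = σ_l f fᵀ + σ_t (I − f fᵀ) from per-node unit fiber vectors. Regional
longitudinal conductivities (S/m): CT 0.7; BB/PM/FO rim 0.5; PV 0.15;
isthmus 0.1; SAN 0.05; AWM (and APG/AVR) 0.2. Anisotropy 1:9 in CT, 1:2
elsewhere, isotropic SAN/isthmus.

**Discretization.** Structured finite differences at 300–700 µm
(530 µm default, the published mesh average): conservative flux form with
arithmetic face averages for the axis terms, centered differences for the
fiber cross terms, mirrored ghost nodes at no-flux boundaries, periodic
rings. Row sums of the assembled operator are exactly zero (diagonal =
−Σ off-diagonal), so uniform states carry no diffusion current and
fiber-sign flips leave the operator bitwise unchanged. Time stepping is
Strang splitting — reaction half-step, diffusion full step, reaction
half-step — at fixed dt = 0.02 ms, with gates advanced by Rush–Larsen
exponential updates and everything else by forward Euler. Interior
half-steps merge (R(h/2)·R(h/2) = R(h)), so the scheme costs one reaction
evaluation per step. A Gershgorin bound on the diffusion spectrum guards
the explicit step: combinations of conductivity and spacing that violate
|diag|·dt ≤ 1 are rejected with an explicit error.

**Fast path.** The production integrator (numba) tabulates all purely
voltage-dependent quantities (gate steady states, Rush–Larsen factors,
the I_Kr/I_K1/I_NaK/GHK voltage factors, the NaCa exponentials) on a
0.02 mV grid with linear interpolation, and refreshes factors that depend
only on the slowly drifting concentrations (reversal potentials, pump
saturation terms, Na ratios) once per 1 ms sampling block — over one
block these change by well under 0.1%. The test suite integrates one
full action potential along both the plain-numpy reference path and the
fast path and requires trace agreement within 1 mV and APD90 agreement
within 1 ms. Refining dt from 0.02 to 0.01 ms changes measured
conduction velocity by < 2%.

**Sv calibration.** The surface-to-volume ratio and stimulus
normalization of the original study are not published. With
C_m'' = 1 µF/cm², Sv was calibrated once by bisection so that a 150-node
AWM-control cable at σ_l = 0.2 S/m conducts at 69 cm/s
(`calibrate_sv`), giving Sv = 4.785e4 m⁻¹, frozen as `DEFAULT_SV`.
All other regional and remodeled conduction velocities are then
parameter-free predictions; they land within ~6% (control) and ~17%
(worst remodeled row, SAN) of the published table, including the
sub-√σ slowing of the slow regions that emerges from discretization at
530 µm — a real feature of coarse-grid propagation, not a fitted one.

**Tissue stimulation.** Rectangular 6 ms pulses on node sets. Bridging
the published total patch current to a per-cell monodomain source is
under-determined (`patch_current_per_cell` documents the derivation; it
lands below the capture threshold), so tissue amplitudes default to a
verified-capture rule: starting from twice the cellular diastolic
threshold, the amplitude doubles until a test pulse activates tissue
outside the stimulated set within 30 ms, and 1.5x that amplitude is used.
This adapts automatically to the electrotonic load, which varies by an
order of magnitude between a plane-wave edge and a point source.

**Activation detection** is an upward V_m crossing of −20 mV recorded
inside the kernel at full dt resolution (sub-step linearly interpolated).
The crossing trails the maximum-upstroke-velocity point by well under a
millisecond, and the offset is common to all nodes, so conduction
velocities — measured by regressing activation time on distance over the
central 25–75% of the path, with a monotonicity check that rejects
collisions — are unaffected.

## Electrogram forward model

Pseudo-unipolar potentials under the large-volume-conductor
approximation: Φ_e = K Σ_nodes [−∇V_m · ∇′(1/r)] ΔV with K = 1 (the
intra/extracellular conductivity ratio is not published, and every
downstream analysis is amplitude-scale-free), ∇V_m by central differences
(one-sided at boundaries), ΔV = dx² × dx for the monolayer wall, and
electrodes ≥ 0.2 mm off the tissue plane. Because the sum is linear in
V_m, each electrode reduces to a fixed lead-field vector; the solver can
accumulate Φ_e(t) during integration, so electrode arrays never require
storing the full V_m history. No truncation radius is applied by
default.

## Signal analysis

Zero-phase (forward–backward) 4th-order Butterworth filters: 40–250 Hz
band-pass, rectification, 20 Hz low-pass, at 1 kHz sampling. Spectra:
records ≥ 4 s, mean removed, zero-padded FFT to the next power of two
with bin width ≤ 0.12 Hz, no taper. The DF search band and the OI
total-power band are both 2–20 Hz (20 Hz is the post-low-pass support;
2 Hz excludes DC leakage); exact DF ties break toward the lower
frequency. OI sums power in 0.75 Hz windows centered on DF and its
2nd–4th harmonics; overlapping windows are merged so no bin is counted
twice. Cycle lengths come from envelope peaks (≥ 30% of the envelope
maximum, ≥ 60 ms apart).

Morphology is classified per activation window (90 ms around envelope
peaks; peaks closer than 50 ms merge, which is what allows the
continuous-activity rule to fire): deflections are signed lobes between
zero crossings exceeding 10% of the trace's maximum absolute deflection;
the isoelectric line is |Φ| below 5% of that maximum for ≥ 10 ms.
Classes: CFAE for more than two *negative* deflections or continuous
supra-isoelectric activity > 50 ms; double for exactly two negative
deflections; single otherwise. Counting negative deflections (rather
than all lobes) keeps the double-potential and CFAE rules mutually
consistent — a classic double potential also carries positive lobes and
would otherwise always classify as fractionated. The 10%/5% thresholds
are configuration knobs; the reference analysis they implement was
visual.

## Synthetic electrogram generator

`make_egm` produces periodic trains of template complexes at 1 kHz:
a biphasic (derivative-of-Gaussian, R-then-S) complex for single
potentials, the same complex plus a second negative deflection 40 ms
later for double potentials, and five alternating low-amplitude
deflections spanning > 50 ms with no isoelectric gap for CFAE; activation
times can carry Gaussian jitter and the trace additive white noise, both
seeded. The generator emulates the *timing and lobe structure* of real
unipolar electrograms — which is what the filtering, spectral and
morphology stages consume — but not far-field superposition, baseline
wander, electrode motion, or amplitude heterogeneity; passing tests on it
validate the analysis chain's selectivity, not its behavior on clinical
recordings. Tissue-derived electrograms from the scenario simulations
close part of that gap.

## Scenario designs (desk scale)

All scenarios are deterministic given their configuration; reentry
induction scans the S2 delay in 10 ms steps across a vulnerability
window estimated from APD plus transit time for the condition.

* **CV table** — per-region 150-node cables at 530 µm (the 1D equivalent
  of the published 150×150 calibration sheet; the wavefront in that sheet
  is planar along the fiber axis).
* **Ring flutter** — ring length = CV × 200 ms (≈ 12.8 cm remodeled,
  241 nodes). Unidirectional start: the first lap is integrated with the
  wrap-around coupling removed, and the ring closes once the front passed
  60% of the circumference. 4.5 s runs; electrograms at 8 electrodes.
* **Block line** — 100×100 remodeled sheet with an embedded CT bar
  (rows 46–53, central 70% of columns, fibers along the bar, 1:9
  anisotropy, longer-APD CT cells). S1 plane wave from the bottom edge,
  premature S2 below the bar's right end; the circuit runs around the
  bar. Bar electrodes see the electrotonic deflection of the blocked
  limb plus the delayed passage — double potentials; remote electrodes
  see single potentials.
* **Focal driver** — continuous corner focus at CL 130 ms on a remodeled
  sheet (150×150 default; tests use smaller sheets and ~4.5 s so spectra
  are computable inside the suite's budget).
* **Spiral** — cross-field S1–S2 on a 100×100 sheet (5.3 cm): S1 plane
  wave from the left edge, S2 over the lower-left quadrant timed into the
  S1 repolarization gradient. In remodeled tissue (wavelength ≈ 5 cm)
  the spiral outlasts 2 s; the same protocol in control tissue
  (wavelength ≈ 2–3× the domain) self-terminates.

## Known limitations

* **Control-cell APD90s.** With the published base parameterization plus
  the conductance table above, the control variants repolarize in
  ~116–203 ms — systematically ~35–45% shorter than the APD90 values
  printed alongside that table (180–307 ms) — while the remodeled
  variants land within ~10–20% (e.g. AWM 68.5 vs 80 ms) and are
  consistent with the independently reported ~60–70% remodeling-induced
  APD reduction for this model family. An extensive search over
  plausible global modifications (sustained-current and pump scalings,
  I_Kr kinetics, Ca-dependent inactivation variants, repolarization-
  fraction conventions) found no coherent parameterization reproducing
  all ten printed values, whose internal pattern (e.g. a 45 ms spread
  between near-identical parameter sets) suggests the source values come
  from a baseline that differs in ways not documented. We ship the
  faithful published equations and report the discrepancy rather than
  fit hidden parameters; the regional *ordering* (AVR shortest, CT
  longest; remodeled < control everywhere) is reproduced except that PM
  and APG — whose parameter sets differ only marginally — swap ranks.
* Remodeling slows conduction here by ~6–14% (via the I_Na inactivation
  shift and the remodeled resting state), less than the reported 9–24%.
* Because the control APD is shorter than the published values (first
  item), the control wavelength is ~10 cm rather than ~19 cm, and the
  5.3 cm control sheet can sustain a slow boundary-assisted reentry
  rather than self-terminating; the remodeled-vs-control contrast
  survives as a large cycle-length difference instead of a
  sustained-vs-terminating dichotomy.
* The monolayer sheet has no wall thickness, fiber rotation, or
  anatomical structure; whole-atria geometry is out of scope.
* Spectral/morphology defaults (bands, thresholds, window widths) are
  reasonable clinical-practice choices, configurable but not fitted to
  any recording database.
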