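# Methods

This note documents the model, the algorithms, the synthetic-data
generator, and the numerical and design choices behind `atriapace`. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Closed-loop circulation model

**Compartments.** Eight volume states — LA, LV, RA, RV, systemic
arteries, systemic veins, pulmonary arteries, pulmonary veins — plus the
mitral flow as a ninth (inertial) state. Vascular compartments are linear
(`p = (V − V0)/C`); the four chambers follow the activation-weighted
elastance law

    p(V, a) = a·c·E_act·(V − V0) + P_ref·(exp(k·(V/V0 − 1)) − 1) + p_peri

The passive exponential permits mild suction below `V0` and is monotone
in volume. A single wall-mechanics model would couple fibre stress and
geometry; this chamber law is deliberately reduced, but it keeps every
lever the HFpEF phenotype needs: relaxation time, passive stiffness,
contractility, wall-mass scale, chamber size. Value-level agreement with
full wall-mechanics models is not claimed anywhere; properties of the
response surface are.

**Activation.** `a(t)` rises as sin² to its single maximum at the twitch
duration `d_act`, then decays exponentially with τ. Atrial onset defines
cycle time zero; ventricular onset follows `pr_interval` later; both wrap
modulo the cycle length, and the previous beat's tail is carried across
the wrap (max of the two contributions) so the waveform stays continuous
at fast rates where PR exceeds diastole. Twitch durations shorten with
rate as `d_ref·(CL/CL_ref)^e` (Bazett-like; e = 0.5 ventricles, 0.3
atria, CL_ref = 1111 ms). Without this restitution a fixed 300-ms systole
leaves no diastole at 140 bpm and the entire fast half of the pacing grid
degenerates.

**Valves.** Ideal diodes (flow = max(Δp,0)/R, no regurgitant leak). The
mitral valve integrates `L·dq/dt = Δp − R·q` with the flow clamped at
zero when closing; the inertance is what separates distinct E and A
inflow waves. An "all valves locked open, zero activation" mode turns the
loop into a passive RC network whose uniform-pressure equilibrium is
computable in closed form (solve ΣV_i(p) = V_tot); the test suite uses it
as an independent oracle.

**Pericardium.** A shared exponential pressure on total heart volume
(`P_ref` 0.4 mmHg, k 5, rest volume 580 mL; slack below rest volume),
added to all four chambers. On by default.

**Integration.** Fixed-step classical RK4 at 1 ms (also the output grid),
compiled with numba. Per-step flow bookkeeping makes blood-volume
conservation exact to floating-point roundoff (every flow enters one
compartment's derivative with + and another's with −), which is why the
1e-6 conservation requirement is met without an adaptive integrator; the
system is non-stiff at this step (fastest eigenmode ≈ 1 ms·0.8). Steady
state is declared when compartment volumes at consecutive beat onsets
differ by < 0.1% (max relative norm), with a 200-beat cap.

**Units.** ms, mmHg, mL, mL/s (L/min for CO) in the public API; seconds
internally.

## Baseline parameterization

The normal reference heart (`normal_chambers`, `default_circulation`) was
set once from textbook haemodynamics: LV `E_act` 4.5 mmHg/mL with
unstressed volume 40 mL gives end-systolic volumes near 60 mL against a
92 mmHg arterial pressure; the passive constants (`P_ref` 0.08 mmHg,
k 1.6) put LVEDP near 8 mmHg at an LVEDV of ~157 mL so a 93-mL stroke
volume at 54 bpm is attainable; atria are thin-walled (`E_act`
0.5–0.7 mmHg/mL) with 100-ms twitches so atrial systole completes before
mitral closure at a 153-ms PR. Vascular compliances/resistances are
standard windkessel values (systemic R ≈ 1.05 mmHg·s/mL at 5 L/min).

## HFpEF phenotype and calibration

`PhenotypeConfig` scales the reference: LV passive stiffness (on
`P_ref`), LV relaxation τ, LV wall mass (on `E_act` and `P_ref` jointly),
atrial dilation (on atrial `V0`), and atrial contractility fraction
(1.0 normal, 0.5 myopathic). `BaselineCalibration.fit()` tunes the first
four by bounded derivative-free minimization (Powell within bounds, then
a Nelder-Mead polish — Powell's line searches stall on the mildly noisy
regulated objective) of the squared relative errors on the baseline
targets mLAP 15.0 mmHg, maximal LA volume 108 mL, E/A 1.1 at 54 bpm under
regulation, with weights (4, 1, 2) reflecting that mLAP is the endpoint
the sweep differences. The fitted scales, kept in
`calibration.CALIBRATED_SCALES` so downstream consumers need not refit,
are ≈ {stiffness 2.56, τ 2.27, mass 1.37, LA dilation 1.41}; regenerate
with `atriapace calibrate`.

## Pressure-flow regulation

Two multiplicative updates hold the operating point across pacing
settings:

    R_sys ← R_sys · [(MAP*/CO*) / (MAP/CO)]^0.5
    V_tot ← V_tot · (MAP*/MAP)^0.125

Both are exactly the identity at the set-points. Design rationale, found
the hard way and verified by the convergence tests:

* The resistance update must *oppose* the measured SVR error (dividing by
  MAP/CO). Multiplying by it is positive feedback — raising R raises
  measured SVR — and diverges.
* CO is measured at the pump (beat-averaged aortic flow). Measuring flow
  through R_sys makes the update self-referential within a beat; the two
  agree at steady state (the flow-consistency invariant).
* Updates are applied only after the transient of the previous update has
  settled (volume state change < 0.1%/beat, 20-beat cap). Updating every
  beat against a still-moving state excites a sustained controller–plant
  limit cycle whose period tracks the venous transport delay.
* The volume gain is smaller than the resistance gain because MAP answers
  a volume change only after several beats, and the loop gain is
  amplified by the stressed-volume fraction. Per-update factors are
  clipped (R ×[0.7, 1.4], V ×[0.95, 1.05]) for robustness far from the
  set-points; near them the clips are inactive.

Added or removed volume enters through the systemic venous compartment.
Convergence = CO and MAP within 0.5% (configurable) for three consecutive
qualifying beats; the loop returns its last parameters either way with a
`converged` flag, and each sweep cell re-converges independently,
warm-started from the reference solution, so grid cells are
order-independent.

## In-silico pacing trial

`PacingSweep` runs one regulated steady-state simulation per (rate, PR)
cell — default 60–140 bpm × 0–300 ms in 10-unit steps — plus the
reference (54 bpm, PR 153 ms; the cohort's sinus PR is the only printed
anchor for the model's intrinsic AV delay). ΔmLAP is the cell mLAP minus
the reference mLAP; the reference row is exactly 0 by construction.
Optima are reported at grid resolution; per-rate optimal PR breaks ties
toward the shorter PR. The decremental-conduction trajectory reads the
grid along a monotone piecewise-linear PR(rate) law anchored at
(55 bpm, 153 ms) and (100 bpm, 228 ms) — the two printed cohort values —
with linear extension beyond the anchors; interpolation in PR is linear,
so the trajectory can never undercut the per-rate minimum (the
AV-sequential dominance property is structural).

**Myopathy attenuation convention.** Each grid's ΔmLAP uses its own
phenotype's reference. Halving atrial contractility raises the myopathic
*reference* mLAP itself (the atrial booster pump matters most during the
long diastole of slow sinus rhythm), so own-reference |ΔmLAP| grows under
myopathy in this model. The attenuation comparison
(`sweep.myopathy_attenuation`) is therefore made against the shared
normal-atrium baseline — both heatmaps anchored to the one 15-mmHg HFpEF
reference — where it expresses the robust physical statement that a weak
atrium cannot unload the left heart as far (its best achievable mLAP is
higher). Both conventions are available in the API.

## Signal pipeline

* **Preprocessing:** 0.5–100 Hz Butterworth band-pass and a 50 Hz notch
  (Q = 30), both zero-phase (forward-backward) so onset timings are not
  shifted — the clinical description does not fix the phase handling, but
  PR measurement demands it — then subtraction of an 800-sample centered
  moving median (shrink-to-valid at the edges) for baseline drift.
* **QRS detection:** classic Pan-Tompkins — 5–15 Hz emphasis, 5-point
  derivative, squaring, 150-ms moving-window integration (causal, so the
  envelope starts rising at QRS energy onset), adaptive signal/noise
  thresholds with 200-ms refractory and search-back — with each detection
  refined to the band-passed waveform's extremum.
* **QRS onset:** back-scan ≤ 80 ms from the R peak for where the 10-ms
  slope of the envelope drops below 5% of its local maximum. **P onset:**
  amplitude back-scan (10% of the P peak) in the 300–50 ms pre-QRS
  window. Both are this package's constructions, validated only against
  synthetic ground truth (the clinical workflow verified onsets
  manually); the end-to-end PR tolerance (10 ms) absorbs their small
  systematic bias.
* **Pacing spikes:** first-difference excursions beyond 8× the rolling
  (1-s block) median absolute deviation of the *signed* difference
  (≈ 5.4 σ for Gaussian noise — an absolute-value MAD would sit at
  ≈ 2.8 σ and flood a 10-min recording with false positives), 100-ms
  refractory.
* **Segmentation:** contiguous spike stretches (gap < 2× the running
  pacing interval; a fresh stretch assumes 1 s until it has its own
  statistics, since the slowest protocol rate is 60 bpm) become paced
  segments with rate = 60/median-interval rounded to the nearest 10 bpm;
  gaps are sinus. Every segment's analysis window is its final 10 s, so
  pacemaker-change transients never contribute.
* **mLAP:** window mean per segment; ΔmLAP per rate = paced window mean
  minus the mean of the two flanking sinus windows (single flank at
  protocol edges, flagged) — the carry-over control is exactly this
  flanking difference, with no further detrending.
* **Wenckebach:** a spike with no QRS within 1.2 pacing cycles is a
  dropped beat; the first paced segment containing one marks the
  Wenckebach rate, and the maximum rate is the rate below it. PR values
  outside (40, 400) ms are flagged and excluded, never silently used.
  Optimal-rate ties break toward the lower rate.
* **Cohort statistics:** Shapiro-Wilk on the paired differences at
  α = 0.05 gates paired-t vs Wilcoxon signed-rank; two-sided p, mean ± SD
  with t-based 95% CI, medians [IQR].

Indices are 0-based with half-open intervals; all reported times are ms.

## Synthetic-data generator

The generator emulates the alternating protocol so the pipeline is
testable without any recording: 30-s segments, paced rates from the
nearest decade above the intrinsic rate to the Wenckebach rate in 10-bpm
steps. Signal morphology is analytic Gaussian bumps (P/QRS/T on the ECG,
a 2-ms biphasic spike on the CS channel, a/v waves on the LA pressure
with a fused high-amplitude wave when PR ≥ half the cycle — the cannon
morphology), so every onset is known exactly. LA-pressure bumps are
zero-meaned per cycle, which makes the programmed mLAP(rate) level the
window mean up to a partial-cycle residual ≲ 0.1 mmHg. Defaults are the
clinical cohort's printed medians: sinus 55 bpm, sinus mLAP 12.8 mmHg, a
Gaussian-well mLAP(rate) dipping 2.3 mmHg at 100 bpm (width 25 bpm), PR
153 ms prolonging 1.7 ms/bpm, Wenckebach at 140 bpm with a deterministic
4:1 drop. Noise defaults (white SD 0.02 mV ECG / 0.2 mmHg LAP, 50 Hz at
0.05, drift 0.15 mV / 0.2 mmHg over 40 s) are plausible catheter-lab
levels chosen once.

What the generator does **not** emulate: real P/QRS morphology variation,
ectopy, respiration, probabilistic Wenckebach periodicity, AF episodes,
catheter artefacts. Passing recovery tests therefore demonstrates the
pipeline's correctness on clean-protocol structure, not robustness to
every clinical artefact.

`generate_cohort` draws per-patient parameters around those defaults with
dispersions matching the cohort's printed moments (e.g. well depth SD
1.4 mmHg); shallow drawn wells can make neighbouring rates statistically
equivalent, which the cohort tests account for.
`model_driven_recording` ties the two halves together: the LA-pressure
channel is the calibrated model's steady beat tiled across each segment
(every scheduled rate divides the 30-s segment into whole beats), with
ECG/CS synthesized from the same timing.

## Problem sizes and runtimes

The shipped configuration is desk-scale on one CPU: the baseline
calibration fit takes seconds; one full 9 × 31 regulated grid runs in
well under a minute (numba-compiled beats, warm-started regulation,
~30–140 beats per cell); pipeline validation uses 10 generator seeds of
full 570-s protocols; the statistics check uses the cohort's n = 75.

## Known limitations

* The chamber law has no fibre-level mechanics, no septal interaction,
  and a single V0 per chamber for both active and passive curves; LVEDV/
  SV trajectories are qualitative.
* AV delay is imposed, not emergent: Wenckebach behaviour exists only in
  the synthetic generator, deliberately matching a protocol where the
  simulated PR is a set parameter.
* Regulation is algebraic feedback, not a baroreflex; no autonomic or
  adrenergic dynamics (atrial pacing notably lacks the adrenergic surge
  of exercise).
* The P-onset detector assumes an upright monophasic P wave, adequate
  for the generator's morphology, untested on biphasic clinical P waves.
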