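# Methods

## Overview

`ricp` simulates rapid ionic current phenotyping (RICP) of induced
pluripotent stem cell derived cardiomyocytes (iPSC-CMs): a 10 s
voltage-clamp protocol whose labeled time points each isolate one ionic
current, recorded through an explicitly modeled patch-clamp measurement
chain, together with 10 s current-clamp (action potential) recordings from
the same in silico cells.  On top of the single-cell pipeline the package
builds populations of models with randomly scaled conductances, computes
Spearman sensitivities of the current-isolating features to the underlying
parameters, correlates segment currents with AP morphology, and generates
a synthetic 39-cell cohort that stands in for experimental recordings.

## The membrane models

Two baseline iPSC-CM profiles are provided (`ricp.models`).  They are
*reconstructions*, not verbatim transcriptions, of the two widely used
iPSC-CM models:

* `kernik` — the Kernik–Clancy-style baseline: its current composition
  (I_Na, I_CaL, I_CaT, I_Kr, I_Ks, I_to, I_K1, I_f, I_NaCa, I_NaK, I_bNa,
  I_bCa, I_PCa), published baseline conductance densities (g_Kr =
  0.218025 nS/pF, g_K1 = 0.13379 nS/pF, g_Na = 9.7206 nS/pF, g_f =
  0.0435 nS/pF, k_NaCa = 1100 A/F, P_NaK = 2.4761 A/F, ...), compartment
  volumes scaled from the ten Tusscher geometry, and a GHK L-type flux.
* `paci` — the Paci (2013, ventricular-like) baseline conductance profile
  (g_Na = 3.671 nS/pF, g_Kr = 0.0299 nS/pF, g_K1 = 0.0281 nS/pF, k_NaCa
  and P_NaK rescaled to the shared Ca2+ handling, no T-type current),
  including the Paci-form Na+ gate steady states (cube-root activation,
  square-root inactivation) whose larger subthreshold availability drives
  its Na+-window pacemaking.

Gate kinetics come from the parent formulations those models were fit
from: ten Tusscher 2004/2006 (I_Na rates, I_CaL, I_to, I_Kr, I_Ks, Ca2+
handling with the ten Tusscher 2004 CICR release gate), Shannon/Demir
(I_CaT), Luo–Rudy (I_Na inactivation rates) and the Paci funny-current
gate.  A small set of per-profile kinetic constants is calibrated so that
each profile reproduces the published baseline behaviour of its source
model under the study configuration (45 pF, 2 GΩ seal): spontaneous
beating with a maximal diastolic potential near −75 mV and cycle lengths
of 1–2 s, a depolarized quiescent branch near −35 mV when repolarizing
current is removed, and the depolarizing response to I_Kr reduction.  The
calibrated constants are:

* hERG inactivation slope (24 mV `kernik`, 50 mV `paci`, reflecting the
  much weaker inward rectification of the Paci I_Kr) and slow hERG
  deactivation at diastolic potentials (deactivation time constants
  approach seconds below −50 mV, as measured for hERG), which lets the
  I_Kr tail participate in setting the diastolic potential;
* the inward-rectifier rectification midpoint/slope plus a small
  weak-rectification component (a Gaussian hump of the open fraction
  around 50 mV positive to E_K) that carries outward current up to about
  −30 mV; without it the depolarized quiescent branch rests unphysiologically
  close to 0 mV;
* the funny-current activation midpoint/slope;
* the L-type permeability of the `kernik` profile, calibrated to the
  source model's peak current density (≈ −5 A/F at a step to 0 mV);
* the `paci` exchanger scale, reduced from the published 4900 A/F because
  the shared Ca2+ handling has a ~10× higher diastolic [Ca2+]i than the
  Paci original; the published value would make the diastolic exchanger
  current several times too inward.

These reconstructions are the substrate of the pipeline, not its
contribution; all downstream machinery (artifact model, protocol,
features, statistics) is model-agnostic.

## Study configuration

Following the recording configuration being emulated: C_m = 45 pF
(volumes are scaled proportionally to C_m, so current densities and Ca2+
dynamics are size-invariant and C_m affects only absolute currents, the
seal-leak density and artifact charging); intracellular Na+ and K+ fixed
to the values found after 1000 s of spontaneous leak-free current-clamp
integration with dynamic concentrations (`init_steady_state`).  The
initialisation run is leak-free because the seal leak is a non-selective
artifact current: including it in a dynamic-concentration run breaks the
ionic charge balance and drains [K+]i.  The shipped per-model initial
states (`ricp/_data/*_init.json`) are the result of this routine followed
by 60 s of settling with the 2 GΩ baseline seal, so simulations start on
the baseline-with-seal attractor.

## Patch-clamp artifact model

The measurement chain (`ricp.artifact`, `ricp.engine.simulate_vc`)
contains: a seal-leak current I_leak = V_m/R_seal (reversal 0 mV; 2 GΩ
baseline); a liquid-junction offset V_ljp = −2.8 mV added to the command;
and membrane charging through the residual access resistance
R_u = (1 − comp_frac)·R_access (20 MΩ, 70% compensated):

    C_m dV_m/dt = (V_cmd + V_ljp − V_m)/R_u − I_ion·C_m − V_m/R_seal

whose conductance-free steady state is the divider
V_m = (V_cmd + V_ljp)·R_seal/(R_seal + R_u).  Supercharging is idealised
as command pre-shaping that brings V_m to the divider target within one
sample at step edges; with supercharging on, the recorded current is
I_out = I_ion + I_leak/C_m (the capacitive transient is supplied by the
supercharge pulse), with it off I_out is the pipette current
(V_cmd + V_ljp − V_m)/(R_u·C_m), which carries the capacitive transient.
The pipette capacitance is assumed fully compensated.  Voltage-clamp
errors during large currents (e.g. I_Na escape) emerge naturally from the
residual-resistance equation.  The artifact module is deterministic;
recording noise belongs to the synthetic cohort.

## Protocol and features

The 10 s protocol fixture (`ricp/_data/ricp_protocol.csv`) reconstructs
the current-isolating waveform: the printed constraints (10 s total, the
I_6mV step at 500 ms measured at 600 ms, and the I_Kr sub-segment —
750 ms at +6 mV, 7 ms at −41 mV, then +9 mV, measured at 1262 ms) are
honoured exactly; the remaining steps are placed so each labeled time
point is dominated by its target current (Na+-inactivating −40 mV
pre-pulse before the I_CaL step, −95 mV recovery before the I_Na step,
+45 mV for I_to, a long −120 mV step for I_K1/I_f activation with the I_f
tail read at −60 mV, and a 2 s +40 mV step for I_Ks).  Features are the
minimum or mean of I_out over a 2 ms window (boundaries inclusive)
centered at 600, 1262, 1986, 2760, 3641, 4300, 5840 and 9040 ms; the
default 0.5 ms sampling puts five samples in each window.

AP features: an AP event is an upward crossing of dV/dt ≥ 2 V/s followed
within 50 ms by a peak ≥ 30 mV above the preceding minimum (robust for
slow I_CaL-driven upstrokes); MP is the mean of per-cycle diastolic
minima (global minimum for quiescent cells; a trailing window whose
minimum falls on the last sample is discarded as an incomplete
diastole); APD90 runs from the time of dV/dt_max to 90% repolarisation of
the per-cycle amplitude; CL is the interval between consecutive
dV/dt_max landmarks; coefficients of variation need ≥ 3 cycles.
Derivatives are central differences after ~1 ms boxcar smoothing
(disabled for noise-free synthetic fixtures in the tests).

## Populations, sensitivity and correlation

`sample_population` draws twelve conductance multipliers (I_Na, I_CaL,
I_Kr, I_Ks, I_to, I_K1, I_f, I_leak, I_NaCa, I_NaK, I_bNa, I_bCa) plus
C_m and R_s factors in [0.25, 4]× baseline, log-uniformly by default
(symmetric in fold change; a uniform option exists because the sampling
law is a modelling choice that affects correlation magnitudes).  "R_s" is
read as the access resistance, since compensation is defined on the
access pathway; the leak multiplier scales 1/R_seal.  C_m and R_s are
measurement-chain parameters: the sampled C_m scales the capacitance the
voltage-clamp chain sees (charging, current normalisation, leak density in
the recording) while the ionic model keeps its configured 45 pF cell —
the study sets the model capacitance and lists C_m alongside R_s among
the artifact quantities.  Each individual
runs the full VC + CC pipeline; failures are flagged and excluded
pairwise (never silently dropped), with >20% failures aborting the run.
Sensitivities are Spearman rank correlations; segment-vs-AP screens
report Spearman rho, a t-approximation p-value and an OLS fit, with
per-segment significance at p < .05 (no multiple-testing correction by
default, a Benjamini–Hochberg option is exposed).

## Synthetic cohort

`generate_cohort` emulates a 39-cell heterogeneous recording session:
per-cell conductance multipliers in [0.25, 4]× (log-uniform), seal
resistance log-uniform over 1–10 GΩ (the experimental seal distribution
is unknown beyond a >300 MΩ pre-rupture criterion; this is a documented
assumption), capacitance uniform over the experimental 18–98 pF range,
and additive white Gaussian current noise (default SD 0.5 A/F — chosen to
visibly perturb but not bury the 2 ms window features; recording noise
was not characterised).  One cell is optionally constructed as a long-APD
outlier by drawing its I_K1/I_f/I_Ks multipliers from [0.1, 0.3] and
re-drawing until its APD90 exceeds twice the cohort median.  CC traces
are 10 s at 0.5 ms sampling.  The cohort reproduces the qualitative
features of the real data — a mix of spontaneous and quiescent-depolarized
cells, recoverable parameter-feature linkages — but not its biological
currents (e.g. the unexplained outward current at +6 mV seen in vitro is
absent by construction), so passing cohort tests demonstrates pipeline
correctness, not model completeness.

## Numerics

LSODA with rtol = atol = 1e-8 for single-cell work (the I_Na activation
gate demands tight tolerances) and a 1 ms step cap in voltage clamp so
protocol edges are never stepped over; each protocol segment is a
separate solver run, making command discontinuities exact.  Population
and cohort runs use rtol = 1e-6, which leaves the extracted features
unchanged to ~1e-4 A/F while roughly halving runtime.  The right-hand
side is numba-compiled.  Population analyses in the tests and the
acceptance script run at n = 150; the g_Kr scan covers 0.1–1.6× baseline
in 16 steps with 10 s simulations per point.

## Known limitations

* The ionic models are calibrated reconstructions; quantities that depend
  on fine kinetics of the source models (exact cycle lengths, AP shapes,
  absolute feature values) differ from the originals even though the
  qualitative structure (current balance, artifact responses, population
  sensitivities) is preserved.
* The leak-free `kernik` profile is quiescent; its spontaneity under the
  study configuration relies on the depolarizing seal-leak drive, whereas
  the published source model also beats without leak.
* Current clamp ignores access resistance and junction offsets
  (perforated-patch emulation); dynamic-clamp protocols are out of scope.
* The amplifier is noiseless and filterless; no ABF/HEKA I/O.
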