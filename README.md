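# ricp — rapid ionic current phenotyping of iPSC-cardiomyocytes in silico

Induced pluripotent stem cell derived cardiomyocytes (iPSC-CMs) are
notoriously heterogeneous: genetically identical cells span tens of mV in
maximal diastolic potential (MP) and several-fold ranges in action
potential duration (APD90), cycle length (CL) and upstroke velocity
(dV/dt_max).  Rapid ionic current phenotyping (RICP) explains that
heterogeneity mechanistically from a single 10 s voltage-clamp recording:
the protocol steps through voltages that isolate, one at a time, eight key
current contributions — I_6mV, I_Kr, I_CaL, I_Na, I_to, I_K1, I_f and
I_Ks — each quantified as the minimum or mean of the recorded total
current I_out (A/F) over a 2 ms window at a labeled time point, and those
per-cell current phenotypes are then correlated against AP features from
the same cells.

This package implements the full in silico side of that method for
electrophysiologists and modellers:

* **Ionic models** (`ricp.models`, `ricp.engine`) — numba-compiled
  iPSC-CM membrane models in two baseline profiles (Kernik–Clancy-style
  and Paci-style conductance sets; see `docs/methods.md` for provenance),
  run with the study configuration: C_m = 45 pF, fixed [Na+]i/[K+]i, and
  per-current conductance multipliers.
* **Patch-clamp artifacts** (`ricp.artifact`) — seal leak
  (I_leak = V_m/R_seal, 2 GΩ baseline), liquid-junction offset (−2.8 mV),
  access resistance (20 MΩ) with 70% series-resistance compensation and
  supercharging; the membrane charges through the residual resistance so
  clamp errors emerge naturally.
* **Protocol & features** (`ricp.protocol`, `ricp.features`) — the 10 s
  RICP command waveform as a machine-readable fixture, the eight labeled
  extraction windows, and AP feature extraction (MP, APD90, CL,
  dV/dt_max, per-feature coefficients of variation).
* **Populations & statistics** (`ricp.population`, `ricp.correlate`) —
  populations of models with twelve conductances plus C_m and R_s scaled
  randomly in [0.25, 4]×, Spearman sensitivity matrices, segment-vs-AP
  correlation screens (with e.g. an `MP > −70 mV` subset predicate), and
  the g_Kr → MP scan.
* **Synthetic cohort** (`ricp.cohort`) — a generated 39-cell stand-in for
  experimental recordings (heterogeneous conductances, per-cell seal
  resistance and capacitance, current noise, a long-APD outlier) so the
  whole pipeline is testable without any data download.

## Worked example

```python
import ricp

cell = ricp.ModelParameters(model_id="kernik",
                            multipliers={"I_Kr": 0.5, "I_leak": 1.0})
rig = ricp.ArtifactParameters()          # 2 GOhm seal, 20 MOhm, 70% comp

i_out = ricp.simulate_vc(cell, rig, ricp.ricp_protocol())
feats = ricp.extract_vc_features(i_out, ricp.ricp_timepoints())
print({k: round(v, 2) for k, v in feats.items()})

v_m = ricp.simulate_cc(cell, rig, duration=10_000.0)
ap = ricp.ap_features(v_m)
print(f"spontaneous={ap.spontaneous} MP={ap.MP:.1f} mV")
```

prints (half-baseline I_Kr, Kernik profile):

```
{'I_6mV': -0.49, 'I_Kr': 0.55, 'I_CaL': -2.86, 'I_Na': -80.74, 'I_to': 3.94,
 'I_K1': -7.02, 'I_f': -2.62, 'I_Ks': 1.25}
spontaneous=True MP=-67.8 mV
```

The I_Kr window (the tail current at +9 mV after a 7 ms recovery step at
−41 mV) reads 0.55 A/F instead of the baseline 0.94 A/F because the cell
has half its hERG conductance; the large negative I_Na and I_K1 windows
are the isolated inward Na+ current and the −120 mV inward-rectifier
response; and the cell still beats, with a maximal diastolic potential of
−67.8 mV (the baseline cell rests near −72 mV; less I_Kr depolarises).

The same things are available from a shell:

```bash
ricp simulate-vc --model kernik --out vc.csv
ricp features vc.csv
ricp population --model paci --n 500 --seed 1 --out pop/
ricp sensitivity --table pop/features.csv --out sens.csv
ricp correlate --table pop/features.csv --feature MP --subset "MP > -70"
ricp cohort --n 39 --seed 1 --out cohort/
ricp gkr-scan --scales 0.1:1.6:16 --out scan.csv
```

Every stochastic command writes a manifest (inputs, seed, version) beside
its outputs.

## Layout

```
src/ricp/        library (models, artifact, protocol, features,
                 population, correlate, cohort, io, cli)
src/ricp/_data/  protocol fixture and cached baseline initial states
tests/           pytest suite (unit, property and acceptance tests)
scripts/         acceptance script
docs/methods.md  model provenance, calibration and numerical choices
```
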