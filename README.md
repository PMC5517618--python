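# myoburst

Simulation and bifurcation analysis of mouse ventricular myocytes on the
road from health to heart failure.

A failing heart shows smaller Ca²⁺ transients, an up-regulated Na⁺/Ca²⁺
exchanger, reduced SERCA uptake and down-regulated K⁺ currents. `myoburst`
implements a detailed whole-cell model of the mouse ventricular myocyte in
two presets — wild type (WT) and a transgenic TNF-α-overexpressing variant
(TG, a heart-failure model) that differs in exactly seven parameters — and
treats the deterioration from WT to TG as a *bifurcation sequence*: rest →
tonic spiking → alternans (period doubling) → bursting → depolarized block.
The package is aimed at cardiac electrophysiology modellers who want to
reproduce, probe or extend that analysis.

The model comprises 15 membrane currents (capacitance-normalized, pA/pF),
Markov gating for I_Na (9 states, including the slow-inactivated states I1
and I2), I_CaL, I_Kr and the ryanodine receptor, Hodgkin–Huxley gating for
the K⁺ currents, and four-compartment Ca²⁺ cycling with troponin/
calmodulin/calsequestrin buffering:

    dV/dt = −Σ I_ion + I_stim,
    d[Ca]_x/dt from J_up, J_rel, J_tr, J_xfer, J_leak, J_trpn.

Two stimulation protocols are built in: standard pulsed pacing (60 pA/pF,
1 ms pulses, BCL 30–150 ms) and a constant injected current (0–1 pA/pF,
applied at t = 20 ms), which turns the cell into an autonomous dynamical
system. A consolidated parameter ε interpolates the seven WT/TG-differing
constants (ε = 0 → WT, ε = 1 → TG). Feature extraction (spike detection
with hysteresis at V_th = −40 mV, APD50, ISI statistics, orbit-diagram
branches) and a regime classifier drive sweep/bisection tools that locate
transition thresholds. A variant I_Na scheme with the slow-inactivation
states removed supports the mechanistic ablation experiment.

## Worked example

```python
from myoburst import (make_parameters, find_resting_state,
                      StimulusProtocol, run_simulation)
from myoburst.features import extract_features

wt = make_parameters("wt")
rest = find_resting_state(wt)
print(f"resting V = {rest.V:.3f} mV, diastolic [Ca]i = {rest.Cai:.4f} uM")

protocol = StimulusProtocol.pulsed(bcl=100.0, total_duration=2.0,
                                   analysis_window=(0.5, 2.0))
trace = run_simulation(wt, protocol, initial=rest)
feats = extract_features(trace, window=(0.5, 2.0))
print(f"regime = {feats.regime}, APD50 = {feats.apd50.mean():.2f} ms, "
      f"AP amplitude = {feats.amplitudes.mean():.1f} mV, "
      f"peak [Ca]i = {trace.Cai.max():.3f} uM")
```

prints

```
resting V = -82.420 mV, diastolic [Ca]i = 0.1150 uM
regime = spiking, APD50 = 3.88 ms, AP amplitude = 114.2 mV, peak [Ca]i = 0.641 uM
```

i.e. the quiescent cell rests at −82.4 mV; paced at 10 Hz it fires the
short (APD50 ≈ 4 ms), large-amplitude action potentials characteristic of
mouse ventricle, with ~0.6 µM Ca²⁺ transients.

The same analyses run from the shell:

```bash
myoburst simulate --genotype wt --protocol constant --istim 0.83 --duration 50
myoburst sweep --control istim --genotype tg --grid 0:1:0.01
myoburst fixtures --directory fixtures
```

Traces are written as HDF5 (`/time`, `/state/{V,Cai,CaNSR,...}`, `/meta`
with the full JSON-encoded protocol/parameters/solver provenance) plus a
`(t, V, Cai)` CSV at 12 significant digits; sweep diagrams export as tidy
CSV (one row per grid point × branch).

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from scratch (~15 min on one CPU): the WT and TG thresholds of
constant-current activity onset (bisection to 0.005 pA/pF on 50-s runs);
the transition positions along the linear ε interpolation at I_stim =
0.55 pA/pF; the lower bounds of the BCL windows with non-periodic Ca²⁺
dynamics under pulsed pacing (1-ms grids, 50-s runs); and the maximum
network-SR Ca²⁺ concentration of the WT model during constant-current
activity. The pipeline is fully deterministic; `--seed` is accepted for
interface compatibility. See `docs/methods.md` for the model description,
numerical choices and known limitations of this re-implementation.
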