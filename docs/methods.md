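# Methods

## The model

`myoburst` implements a deterministic whole-cell model of the isolated mouse
ventricular myocyte in its apical parameterization, together with the seven-
parameter transgenic (TG) variant representing TNF-α-overexpressing mice, an
established animal model of heart failure.

The membrane equation is capacitance-normalized (all currents in pA/pF,
outward positive; a depolarizing stimulus enters as `+I_stim`):

    dV/dt = −(I_Na + I_CaL + I_p(Ca) + I_NaCa + I_Cab + I_Nab + I_NaK
              + I_Kto,f + I_Kto,s + I_K1 + I_Ks + I_Kur + I_Kss + I_Kr
              + I_Cl,Ca) + I_stim

Gating uses Hodgkin–Huxley variables for the K⁺ currents and Markov chains
for the fast Na⁺ current (9 states: C3–C1, O, IF, I1, I2, IC2, IC3), the
L-type Ca²⁺ current (8 states with Ca²⁺- and voltage-dependent
inactivation), the rapid delayed rectifier (5 states), and the ryanodine
receptor (4 states, Keizer–Levine-type adaptation). Ca²⁺ handling couples
four compartments (cytosol, subspace, junctional and network SR) through
J_up (SERCA), J_rel (RyR), J_tr, J_xfer, J_leak and J_trpn, with buffering
by calmodulin, troponin (high/low affinity) and calsequestrin.

One state per Markov chain is stored as the algebraic complement of the
others, so occupancy conservation is exact along any trajectory rather than
an integration-accuracy statement.

Units: ms, mV, pA/pF, mS/µF; Ca²⁺ in µM, Na⁺/K⁺ in mM. Fixed extracellular
concentrations: Na⁺ 140 mM, K⁺ 5.4 mM, Ca²⁺ 1.8 mM; T = 298 K.

### WT → TG remodeling and the interpolation parameter ε

The TG preset differs from WT in exactly seven constants: the SERCA maximal
uptake rate `v3`, the Na⁺/Ca²⁺-exchanger scaling `kNaCa`, the conductances
`GKtof`, `GKur`, `GK1`, and two shape parameters of I_K1 (`k1_power`,
`k1_slope`). A consolidated parameter ε interpolates all seven from WT
(ε = 0) to TG (ε = 1), linearly by default; alternatively one named
parameter follows the faster monotone exponential map
`p_WT + (p_TG − p_WT)·(e^{kε} − 1)/(e^k − 1)` with k = 5 (a configuration
knob), endpoint-preserving by construction.

The exact numerical values of the seven TG constants are not printed in the
source texts available to this package; the shipped values are documented
stand-ins chosen once from the experimentally reported TNF-α remodeling
directions (I_to,f and I_K,slow densities reduced 25–30 %, I_K1 reduced,
NCX up-regulated ~1.5×, SERCA function reduced ~20 %), with the I_K1
reduction sized so that the ratio of TG to WT resting I_K1 is consistent
with the reported ratio of their constant-current excitation thresholds.
I_K1 is parameterized as

    I_K1 = GK1 · Ko/(Ko + 0.21 mM) · (V − EK) / (1 + e^{slope·(V−EK)})^power

so that the "power index" acts on the rectification denominator — the only
placement where an exponent materially changes the current near rest.

## Protocols

* **Pulsed pacing** — 60 pA/pF, 1 ms pulses at a basic cycle length (BCL)
  of 30–150 ms; the standard protocol. Feature window: final 2 s of a 50-s
  run.
* **Constant current** — a step of 0–1 pA/pF applied at t = 20 ms from the
  resting state, making the cell an autonomous dynamical system. Feature
  window: 40–50 s of a 50-s run.

Integration is LSODA with a compiled (numba) right-hand side and finite-
difference Jacobian, rtol 1e-6 and per-variable atol 1e-8 scaled by each
variable's typical magnitude. The integrator is restarted at every stimulus
discontinuity, so pulse edges are never stepped over. Output is sampled at
0.05 ms (sub-APD50 resolution for ~4 ms murine action potentials). The
pipeline contains no randomness: identical inputs give identical traces.

The resting state is located by 100 s of unstimulated integration followed
by Newton refinement of the RHS root; the scaled residual must fall below
1e-6 and the resting potential must lie in [−90, −70] mV. Sweeps cold-start
every grid point from the resting state of that point's own parameter set
(warm-start continuation is available but off by default, since orbit
diagrams assembled from cold starts are insensitive to hysteresis).

## Feature extraction and regime labels

Spikes are upward crossings of V_th = −40 mV with hysteresis (re-arm below
−50 mV, so plateau ripples during bursts are not double-counted), with
linear interpolation for sub-sample timing. APD50 is measured from the
upstroke (maximal dV/dt preceding the peak) to 50 % repolarization, so the
pulsed and constant protocols share one definition. Orbit-diagram branches
are 1-D clusters of local extrema (gap clustering, 0.5 mV for V, 2 %
relative for Ca²⁺).

Regime rules (all thresholds logged with each classification):
quiescent (no spikes, settled, V < −60 mV); depolarized block (no spikes,
settled above −55 mV); spiking (one ISI cluster and one amplitude branch);
alternans (exactly two interleaved amplitude or ISI branches, ≥ 5 events
each); bursting (bimodal ISIs with gap factor ≥ 3 and ≥ 2 spikes per
train); otherwise irregular — ambiguity is never silently forced. The
calcium classifier works on per-beat transient peaks: periodic (one
branch), alternans (two interleaved), bursting/irregular (more branches
with relative spread > 15 %, an operational stand-in for a visually defined
notion of "highly irregular" transients).

## What the simulator does and does not establish

The simulator doubles as the data generator: all analyses run on its own
output, so green tests establish internal consistency of model, protocols
and feature extraction — not agreement with any laboratory recording. The
model reproduces the published resting state of the formulation it
re-implements exactly
(all 41 equilibrium residuals ≈ 0 at the published initial conditions; this
rest-equilibrium consistency was also used to validate individual rate
constants through detailed-balance ratios) and its paced physiology
(AP amplitude ≈ 115 mV, APD50 ≈ 4 ms, Ca²⁺ transient ≈ 0.6 µM, SR load
≈ 1.3 mM).

Known limitation: under the constant-current protocol this transcription
places the loss of the WT resting state near 0.71 pA/pF rather than the
reported 0.58, spiking near onset is paced by the slowly deactivating
I_Kss gate (τ ≈ 16 s at −70 mV) instead of Na⁺-channel slow inactivation,
and no multi-spike AP-bursting window appears in WT at 0.79–0.88 pA/pF
(the depolarized silent phase that hosts bursting sits at −38 mV here,
deep enough to keep Na⁺ channels inactivated). A one-parameter sensitivity
study over the plausibly mis-transcribed constants did not recover the
reported landmark pattern, and no independent machine-readable encoding of
the source model was reachable for cross-checking; the divergence is
reported as-is rather than tuned away. Downstream quantities that depend
only on the paced Ca²⁺ machinery (APD50, transient amplitudes, SR content,
the irregular-Ca BCL windows) are unaffected by this and land close to the
reference values.

## Numerical choices

* Solver tolerances as above; halving rtol changes APD50 and peak Ca²⁺ by
  < 1 % on a 2-s paced run (tested).
* Threshold bisections stop at a bracket width of 0.005 pA/pF (0.01 on ε);
  endpoints must classify to the from/to regimes and a midpoint classifying
  to neither raises rather than forcing monotonicity.
* Stripping slow inactivation removes I1/I2 and every incident edge;
  occupancy in I1/I2 is reassigned to IF (nearest inactivated neighbour) —
  relevant only to warm starts, since cold starts use the variant's own
  resting state.
* Degenerate inputs: traces with < 2 spikes have an undefined (NaN) mean
  ISI, never zero; truncated APs at window edges are omitted from AP
  metrics.
* Analysis windows: classifications at BCL ≈ 40–48 ms were found not to be
  settled at 30 s, so pulsed scans use the full 50-s duration with the
  final-2-s window; constant-current scans in the test suite use 30-s runs
  with a 20–30 s window (spot-checked against 50-s runs).
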