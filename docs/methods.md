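# Methods

## Model

The package simulates the population-averaged glutamatergic response evoked
by Schaffer-collateral field stimulation in a CA1 pyramidal cell, as a system
of seven first-order ODEs: two for the somatic and dendritic membrane
potentials of a passive two-compartment cell, one for AMPA receptor gating,
two for glutamate concentration in the synaptic cleft and in a lumped
perisynaptic compartment, and two for short-term plasticity (presynaptic
facilitation `F` and AMPA desensitization/depression `D`).

Key assumptions, in the order they matter:

- **Receptor placement and sensitivity.** AMPA receptors sit in the cleft
  and see the large, brief cleft transient; NMDA receptors are peri- and
  extrasynaptic and see the small, slow perisynaptic concentration. Their
  activation curves are saturation functions with half-max at 1000 μM
  (Hill exponent 1.6) and 4.7 μM respectively — the ~200-fold sensitivity
  difference is what makes transporter blockade prolong NMDA currents while
  leaving per-peak AMPA kinetics nearly untouched. NMDA gating is
  instantaneous in the perisynaptic concentration (no activation delay is
  modelled, deliberately); the fraction activated by background glutamate is
  treated as tonically desensitized and subtracted. If the perisynaptic
  concentration transiently dips below background, the raw gate would turn
  negative; it is clipped at zero (with a warning in the public function),
  since the subtraction models a desensitized fraction, not a negative
  conductance.
- **Glutamate transport.** Release enters the cleft as square flux pulses
  (amplitude `W·ν` = 200 μM/ms, duration 1 ms; only the product of spike
  contribution and flux is identifiable, so a single parameter is used).
  The cleft exchanges with the perisynaptic pool on τ_glu = 2.9 ms scaled by
  the volume ratio β = 66; the perisynaptic pool drains to the bulk level on
  τ_diff = 1.17 s and is pumped by EAAT2 with maximum rate 0.31 μM/ms, a
  Michaelis–Menten glutamate factor (k_½ = 28 μM) and a sodium-gradient
  factor (half-max gradient 50 mM, exponent 1.5) that is constant under
  fixed sodium levels and precomputed per run. There is deliberately no
  uptake term in the cleft: the transporters are astrocytic and perisynaptic.
  Transporter blockade = uptake rate zero plus a nonzero background
  concentration (2 μM).
- **Electrotonics.** The cell is passive (no spiking conductances): membrane
  time constant 11 ms, dendrite/soma area ratio γ = 2, electrotonic
  parameter l = 1.3. Receptors are dendritic, so both the synaptic driving
  force and the magnesium-block factor are evaluated at the dendritic
  potential; a `drive_at_soma` flag switches to the somatic potential for
  comparison. Under somatic voltage clamp only the soma is held — the
  dendritic potential keeps evolving, and this space-clamp effect is what
  makes NMDA amplitudes at −20 and +40 mV holding comparable even though the
  nominal driving forces differ two-fold. The one-compartment reduction
  (γ→0, l→0, synaptic current delivered at the soma) is available as a
  clamp option and loses exactly this property.
- **Plasticity.** Facilitation is driven by perisynaptic glutamate (a proxy
  for presynaptic depolarization through metabotropic/extrasynaptic
  receptors) rather than by spike timing: resting value 0.42, growth rate
  64 ms⁻¹ scaled by c/k_½, decay τ_F = 0.16 ms. Desensitization recovers on
  410 ms and is depleted at 1.3 s⁻¹ times the instantaneous AMPA activation.
  Presynaptic depression is folded into `D` rather than modelled separately.

## Parameters and units

All parameters live in four dataclasses (`NeuronParams`, `ReceptorParams`,
`TransportParams`, `PlasticityParams`) with the reference values above as
defaults; per-cell somatic conductance (8, 12, 8.2, 9 nS) and leak reversal
(−70, −69, −34, −4 mV) for the four reference cells are kept as a fixed
table. The strongly depolarized leak reversals of cells 3–4 come from
cesium-based pipette solutions and are accepted as cell-specific constants.
Native units are ms / mV / nS / μM (sodium in mM), so conductance × voltage
gives pA directly; published tables that mix seconds and milliseconds are
normalized at load time (`{value: 1.17, unit: s}` in a config file, or the
`from_seconds` / `per_second` helpers), with round-trip tests.

τ_A, the AMPA closing time, is not part of the published parameter table; the
package default is 2 ms, a standard deactivation time constant for
hippocampal AMPA receptors. It is a free parameter in every fitting study,
so only the synthetic ground truth depends on the default.

## Numerics

- The system is stiff (τ_F = 0.16 ms against τ_diff = 1170 ms), so
  integration uses LSODA with rtol 1e-6 / atol 1e-9 by default. The time
  axis is split at every square-pulse edge — within a segment the release
  flux is constant, so the solver never steps over a pulse — and the step is
  capped at 0.1 ms inside pulses. Tightening the tolerances tenfold moves
  peak currents by well under 0.1% (tested).
- Because τ_F is far below every other time scale, `F` can be slaved to its
  quasi-steady state `F* = (F₀ + τ_F H_F c/k)/(1 + τ_F H_F c/k)`, reducing
  the order from 7 to 6 (`use_qss=True`). The reduced and full systems agree
  to better than 1% on all traces (regression-tested); the fitting pipeline
  uses the reduced form for speed.
- Resting states are solved with a Newton–Krylov-free hybrid root solve
  started from the analytic guess and verified to residual < 1e-9 in every
  component. In blockade the resting facilitation is the quasi-steady value
  at the 2 μM background (≈ 0.66 instead of 0.42), which is what amplifies
  the first response of a train under blockade.
- Inter-train intervals (20 s in the emulated experiments) exceed every
  model time scale, so each train is simulated from the resting state rather
  than integrating the quiescent gap.
- Concentrations are clipped at zero inside the right-hand side and on
  output; trajectories are asserted non-negative in tests.
- The dendritic-current reconstruction `(l/2 τ_m d/dt + 1 + l/2) I_VC`
  inverts the passive clamp exactly in continuous time; the implementation
  uses second-order central differences (one-sided at the ends) with
  optional moving-average pre-smoothing, and recovers a known dendritic
  current to < 0.5% on a passive test case.
- Decay time of a response is not uniquely defined by convention, so the
  default metric is the time for the deviation to fall from its peak to 1/e
  of it, with 10–90% fall time and a log-linear exponential fit as
  configurable alternatives. Per-peak kinetics within a train are measured
  on the transient above each inter-pulse window's end level, so slow
  inter-pulse tails do not masquerade as changed peak shape. A flat trace
  reports a missing decay time rather than zero.

## Fitting

The loss is the mean-squared error between simulated and recorded traces on
the recording's own grid (baseline = pre-stimulus mean, subtracted from both
sides), summed over traces with optional weights (default 1 per trace).
Minimization is Nelder–Mead on transformed parameters — log for positive
quantities, logit for fractions — which keeps the search in the physical
domain without bound clipping. The staged schedule mirrors the experimental
logic: (1) electrotonic parameters, by reconstructing the dendritic current
from a voltage-clamp trace and reproducing the matching current-clamp
voltage; (2) AMPA-dominated traces; (3) NMDA traces; (4) joint refinement,
each stage warm-starting the next. Per-cell G_s and U_L stay fixed (as
measured values would be); all other parameters are shared across cells.
Stage 1 is exact only for the linear cable — when the synthetic CC trace
comes from the full nonlinear model the reconstruction is biased by the
driving-force difference between clamp modes, which is one reason the final
joint stage exists. Fits are deterministic and bit-for-bit reproducible for
a fixed seed.

Robustness is probed the same way the procedure itself was validated:
restart the whole schedule from parameters perturbed uniformly within ±50%
and report the maximum relative deviation of the recovered values. On the
noiseless synthetic four-trace dataset (AMPA ±blockade at −80 mV, NMDA
±blockade at −20 mV; 1 ms sampling; function-evaluation caps of 450/600/1300
per stage) the seven transport/receptor parameters return to their
generating values to well within 20%.

## Synthetic data

The generator emulates the recording design the model was built for: four
cells, 5×50 Hz trains, somatic voltage clamp at −80 mV (AMPA-isolated,
±blockade), −20 mV (NMDA-isolated, ±blockade) and +40 mV, plus a mixed
VC/CC pair for the electrotonics stage. Pharmacological isolation is
emulated by zeroing the blocked conductance. Noise is additive i.i.d.
Gaussian with σ defaulting to 5% of each trace's peak (recording noise was
not quantified in the source experiments; 5% is a typical evoked-EPSC
signal-to-noise level). What the generator does *not* emulate: stimulus
artifacts, series-resistance and liquid-junction errors, baseline drift,
trial-to-trial release variability, and imperfect pharmacological isolation.
Passing recovery tests on these data therefore demonstrate identifiability
of the model given its own assumptions, not robustness to real-recording
systematics.

## Known limitations

- **Input conductance formula.** The closed form G_in = G_s(3+2γ)/(3+γ)
  conventionally used to fix G_s from a measured input resistance is not the
  steady state of the two-compartment equations as written, which give
  G_in = G_s(1+2γ/(l+2)); the two coincide only at l = 2γ+4. Both are
  provided (`input_conductance`, `input_conductance_from_equations`) and
  each is tested against its own reference.
- **Perisynaptic accumulation.** With the reference parameters a single
  pulse raises perisynaptic glutamate by ~1.4 μM, but mass balance makes the
  5-pulse 50 Hz train accumulate to ~7 μM at the fifth pulse: each pulse
  transfers W·ν·Δt·F/β ≈ 1.3–2.4 μM into the perisynaptic pool while uptake
  plus bulk diffusion remove < 0.5 μM per 20-ms interval. Literature
  estimates of 1–3 μM for perisynaptic transients should therefore be read
  per response, not as the train maximum, under this parameter set.
- Single lumped synapse population; no spatial cable beyond two
  compartments, no electrodiffusion (the voltage dependence of NMDA response
  shapes is reproduced by electrotonics alone, without it), no multi-state
  receptor schemes, no astrocytic GABA co-release or metabolic/vascular
  coupling, no global optimization or formal uncertainty quantification in
  the fitting module.
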