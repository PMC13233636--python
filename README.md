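# glusyn

Biophysical simulation of glutamatergic synaptic transmission at the
hippocampal CA3→CA1 (Schaffer collateral) synapse, for computational
neuroscientists who need a synapse model that keeps neurotransmitter dynamics
explicit yet stays cheap enough for network work: seven ordinary differential
equations covering glutamate release and two-compartment diffusion,
astrocytic EAAT2 uptake, AMPA/NMDA receptor gating with their very different
glutamate sensitivities, glutamate-driven short-term plasticity, and passive
soma/dendrite electrotonics. The package also ships the staged least-squares
machinery used to fit such a model to patch-clamp traces, and a synthetic
recording generator that emulates the voltage-clamp/current-clamp experiments
the model describes.

## The model

State variables: somatic and dendritic potentials `U, U_d` (mV), AMPA gate
`m_AMPA`, cleft and perisynaptic glutamate `C_glu, C_glu^periph` (μM),
facilitation `F` and desensitization `D`.

Passive two-compartment cell (current clamp):

    τ_m dU/dt   = −(U − U_L) + (2γ/l)(U_d − U) + I_inj/G_s
    τ_m dU_d/dt = −(U_d − U_L) − (2/l)(U_d − U) + I_d/(γ G_s)

with `I_d = I_AMPA + I_NMDA`,
`I_AMPA = ḡ_AMPA m_AMPA (U_rev − U_d)` and the NMDA current additionally
gated by the Jahr–Stevens magnesium factor
`1/(1 + ([Mg]_o/3.57 mM) e^(−0.062 V))`. Under somatic voltage clamp `U` is
held at `V_h`, the dendrite keeps its own dynamics (the space-clamp problem),
and the recorded current is `I_VC = 2(G_s γ/l)(U_d − U_d⁰)`.

Receptor sensitivities are saturation functions of glutamate concentration —
`S_AMPA(c) = 1/(1 + (1000 μM/c)^1.6)` in the cleft,
`S_NMDA(c) = 1/(1 + 4.7 μM/c)` perisynaptically — so NMDA receptors respond
to concentrations two orders of magnitude lower than AMPA receptors. The
AMPA gate relaxes to `S_AMPA(C_glu)·D` with closing time τ_A; the NMDA gate
follows `S_NMDA(C_glu^periph) − S_NMDA(C_glu⁰)` instantaneously.

Glutamate is released into the cleft as square flux pulses scaled by the
facilitation `F`, exchanges with the perisynaptic compartment (time τ_glu,
volume ratio β), drains toward the bulk level `C_glu⁰` (time τ_diff), and is
removed perisynaptically by EAAT2 at rate
`α^periph · f_Na · C/(k_½ + C)`. Transporter blockade (TFB-TBOA) is modelled
as `α^periph = 0` with a nonzero background `C_glu⁰` — which is exactly what
prolongs NMDA-receptor currents while leaving per-peak AMPA kinetics intact.

## Worked example

```python
import numpy as np
import glusyn as g

params = g.table_params(cell_id=3)          # reference parameters, cell-3 G_s/U_L
train  = g.StimulusTrain.periodic()         # 5 pulses at 50 Hz
clamp  = g.ClampSpec(mode="vc", V_h=-20.0)

ctrl = g.simulate(params, train, clamp, g.Condition.control(),      t_end=1500.0)
tboa = g.simulate(params, train, clamp, g.Condition.blockade(2.0),  t_end=3500.0)

for name, res in [("control", ctrl), ("blockade", tboa)]:
    m = g.metrics(res)
    print(name, "peak", round(max(abs(np.array(m.peak_amplitudes))), 1), "pA,",
          "decay", round(m.decay_time, 1), "ms")
```

prints (mixed AMPA+NMDA response at −20 mV holding):

    control peak 403.9 pA, decay 153.4 ms
    blockade peak 409.5 pA, decay 962.4 ms

Blocking uptake prolongs the response decay several-fold because
perisynaptic glutamate is then cleared only by slow bulk diffusion. With the
NMDA component isolated (`gbar_ampa=0`, as in the DNQX experiments) the
effect is starker still — a control peak of 246 pA decaying in 224 ms versus
a blockade peak of 194 pA decaying in ~2.2 s: slower decay with a *smaller*
peak, because background glutamate holds part of the receptor pool
desensitized — while AMPA-isolated per-peak decay changes by under 10%.

The same runs are available from the shell:

```bash
glusyn simulate --mode vc --vhold -20 --condition tboa --out tboa.tsv
glusyn generate --out-dir data/ --seed 1          # synthetic 4-cell dataset
glusyn fit --data-dir data/ --out fit_report.txt  # staged Nelder-Mead fit
glusyn metrics --trace data/cell3_nmda_-20mV_control.tsv
```

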