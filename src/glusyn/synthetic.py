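"""Synthetic patch-clamp recordings standing in for the slice experiments.

No experimental traces are deposited for this preparation, so the package
ships a generator that forward-simulates the experimental design and adds
recording noise.  The emulated design follows the four reference cells:

* cell 1 (G_s = 8 nS, U_L = -70 mV): a somatic VC recording of the mixed
  glutamatergic response and the matching CC voltage recording, control;
* cell 2 (12 nS, -69 mV): AMPA-isolated currents at V_h = -80 mV, control
  and transporter blockade (NMDA contributes almost nothing at -80 mV
  because of the magnesium block);
* cell 3 (8.2 nS, -34 mV): NMDA-isolated currents at -20 mV (control) and
  at +40 mV (control) — the voltage-dependence pair;
* cell 4 (9 nS, -4 mV): NMDA-isolated current at -20 mV under blockade.

Each trace uses the 5-pulse 50 Hz stimulation protocol; successive trains in
the experiment are 20 s apart, long past every model time scale, so each
train is simulated from the resting state.  Noise is additive i.i.d.
Gaussian with standard deviation ``noise_sigma`` times the peak deviation of
the noiseless trace.
"""

from __future__ import annotations

from dataclasses import replace as _replace
from typing import Optional

import numpy as np

from .glutamate_transport import StimulusTrain
from .io import Recording
from .neuron_electrotonics import ClampSpec
from .params import ModelParams, neuron_params_for_cell
from .simulator import Condition, SolverOptions, simulate

__all__ = ["generate_synthetic_dataset", "PROTOCOL_TABLE"]

#: (key, cell_id, isolation, mode, V_h, condition, duration_ms)
PROTOCOL_TABLE = (
    ("cell1_mixed_vc_control", 1, "mixed", "vc", -70.0, "control", 300.0),
    ("cell1_mixed_cc_control", 1, "mixed", "cc", None, "control", 300.0),
    ("cell2_ampa_-80mV_control", 2, "ampa", "vc", -80.0, "control", 300.0),
    ("cell2_ampa_-80mV_tboa", 2, "ampa", "vc", -80.0, "tboa", 300.0),
    ("cell3_nmda_-20mV_control", 3, "nmda", "vc", -20.0, "control", 700.0),
    ("cell3_nmda_+40mV_control", 3, "nmda", "vc", 40.0, "control", 700.0),
    ("cell4_nmda_-20mV_tboa", 4, "nmda", "vc", -20.0, "tboa", 700.0),
)


def _condition(label: str, params: ModelParams) -> Condition:
    if label == "control":
        return Condition.control()
    return Condition.blockade(params.transport.c0)


def generate_synthetic_dataset(
    params: Optional[ModelParams] = None,
    noise_sigma: float = 0.05,
    seed: int = 0,
    dt: float = 0.5,
    protocol: Optional[StimulusTrain] = None,
    solver: Optional[SolverOptions] = None,
    subset: Optional[list] = None,
) -> dict:
    """Forward-simulate the recording design and return ``{key: Recording}``.

    ``noise_sigma`` is the noise standard deviation as a fraction of each
    trace's peak deviation from baseline (0 reproduces the simulator output
    exactly); the generator is deterministic for a fixed seed.  ``subset``
    restricts generation to the given keys.
    """
    base = ModelParams() if params is None else params
    rng = np.random.default_rng(seed)
    out = {}
    for key, cell, isolation, mode, v_h, cond_label, duration in PROTOCOL_TABLE:
        if subset is not None and key not in subset:
            continue
        p = base.replace(neuron=neuron_params_for_cell(cell, tau_m=base.neuron.tau_m,
                                                       gamma=base.neuron.gamma, l=base.neuron.l))
        rp = p.receptor
        if isolation == "ampa":
            p = p.replace(receptor=_replace(rp, gbar_nmda=0.0))
        elif isolation == "nmda":
            p = p.replace(receptor=_replace(rp, gbar_ampa=0.0))
        clamp = ClampSpec(mode=mode, V_h=v_h)
        cond = _condition(cond_label, base)
        train = protocol if protocol is not None else StimulusTrain.periodic(
            amplitude=base.transport.w_nu_pulse, duration=base.transport.dt_pulse
        )
        opts = solver if solver is not None else SolverOptions(dt=dt)
        res = simulate(p, train, clamp, cond, t_end=duration, solver=opts)
        clean = res.recorded.copy()
        peak = np.max(np.abs(clean - clean[0]))
        sigma = noise_sigma * peak
        noisy = clean + rng.normal(0.0, sigma, size=clean.shape) if sigma > 0 else clean
        out[key] = Recording(
            time=res.time,
            values=noisy,
            cell_id=cell,
            mode=mode,
            v_hold=v_h,
            condition=cond_label,
            isolation=isolation,
            units="pA" if mode == "vc" else "mV",
            noise_sigma=float(sigma),
            seed=seed,
        )
    return out
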