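"""Short-term plasticity driven by glutamate concentration.

Presynaptic facilitation F(t) grows toward 1 in proportion to the
perisynaptic glutamate level (a proxy for presynaptic depolarization through
metabotropic/extrasynaptic receptors) and relaxes back to its resting value F0
with time constant tau_F.  AMPA receptor desensitization/depression D(t)
recovers toward 1 with tau_D and is depleted in proportion to the current AMPA
activation.  Because tau_F is far smaller than every other time scale in the
model, F can be replaced by its quasi-steady state, reducing the ODE system
order by one.
"""

from __future__ import annotations

import numpy as np

from .params import PlasticityParams
from .receptor_kinetics import s_ampa

__all__ = [
    "facilitation_rhs",
    "desensitization_rhs",
    "facilitation_qss",
    "desensitization_fixed_point",
]


def facilitation_rhs(F, c_periph, p: PlasticityParams):
    """dF/dt (1/ms): relaxation to F0 plus saturating glutamate-driven growth."""
    F = np.asarray(F, float)
    drive = p.H_F * np.asarray(c_periph, float) / p.k_half_glu
    out = (p.F0 - F) / p.tau_F + drive * (1.0 - F)
    return out if out.ndim else float(out)


def desensitization_rhs(D, c_cleft, p: PlasticityParams, s_ampa_fn=None):
    """dD/dt (1/ms): recovery toward 1 minus activation-proportional depletion.

    ``s_ampa_fn`` maps cleft glutamate to the AMPA activation used in the
    depletion term; it defaults to the package sensitivity function evaluated
    with receptor defaults and is injectable so receptor and plasticity
    parameterizations stay consistent in the assembled model.
    """
    if s_ampa_fn is None:
        from .params import ReceptorParams

        rp = ReceptorParams()
        s_ampa_fn = lambda c: s_ampa(c, rp)  # noqa: E731
    D = np.asarray(D, float)
    out = (1.0 - D) / p.tau_D - p.H_D * D * np.asarray(s_ampa_fn(c_cleft), float)
    return out if out.ndim else float(out)


def facilitation_qss(c_periph, p: PlasticityParams):
    """Quasi-steady-state facilitation: the fixed point of dF/dt at frozen c_periph.

    ``F* = (F0 + tau_F*H_F*c/k) / (1 + tau_F*H_F*c/k)`` — equals F0 at c = 0
    and saturates at 1 for large concentrations.
    """
    x = p.tau_F * p.H_F * np.asarray(c_periph, float) / p.k_half_glu
    out = (p.F0 + x) / (1.0 + x)
    return out if out.ndim else float(out)


def desensitization_fixed_point(c_cleft, p: PlasticityParams, s_ampa_fn):
    """Resting D solving dD/dt = 0 at frozen cleft concentration."""
    s = np.asarray(s_ampa_fn(c_cleft), float)
    out = 1.0 / (1.0 + p.tau_D * p.H_D * s)
    return out if out.ndim else float(out)
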