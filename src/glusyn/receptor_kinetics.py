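"""AMPA and NMDA receptor sensitivity functions and gating dynamics.

AMPA receptors sit inside the synaptic cleft and gate with a first-order ODE
whose target is the product of a Hill-type sensitivity of the cleft glutamate
concentration and the desensitization factor D(t).  NMDA receptors are peri-
and extrasynaptic and so much more sensitive to glutamate that their gating is
treated as instantaneous in the perisynaptic concentration, with the fraction
tonically activated (hence desensitized) by background glutamate subtracted.
"""

from __future__ import annotations

import warnings

import numpy as np

from .params import ReceptorParams

__all__ = ["s_ampa", "s_nmda", "ampa_gate_rhs", "nmda_gate"]


def _check_nonneg(c, name: str):
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError(f"{name} must be non-negative (glutamate concentration)")
    return c


def s_ampa(c, p: ReceptorParams):
    """AMPA receptor activation as a function of glutamate concentration (uM).

    Hill function ``c**h / (c**h + ec50**h)`` with half-activation at
    ``p.ec50_ampa`` and exponent ``p.hill_ampa``; written in the form that is
    exact at c = 0 (returns 0) instead of dividing by the concentration.
    Strictly increasing, saturating at 1.
    """
    c = _check_nonneg(c, "c")
    ch = c ** p.hill_ampa
    out = ch / (ch + p.ec50_ampa ** p.hill_ampa)
    return out if out.ndim else float(out)


def s_nmda(c, p: ReceptorParams):
    """NMDA receptor activation: ``c / (c + ec50)``, half-max at ``p.ec50_nmda`` uM."""
    c = _check_nonneg(c, "c")
    out = c / (c + p.ec50_nmda)
    return out if out.ndim else float(out)


def ampa_gate_rhs(m, c_cleft, D, p: ReceptorParams):
    """Time derivative (1/ms) of the AMPA gating variable m.

    First-order relaxation toward ``S_AMPA(c_cleft) * D`` with the receptor
    closing time ``p.tau_A``; the fixed point under constant input is that
    product, and the relaxation is exponential with time constant tau_A.
    """
    return (s_ampa(c_cleft, p) * np.asarray(D, dtype=float) - np.asarray(m, dtype=float)) / p.tau_A


def nmda_gate(c_periph, c0, p: ReceptorParams, *, clip: bool = True, warn: bool = True):
    """Instantaneous NMDA gating: ``S_NMDA(c_periph) - S_NMDA(c0)``.

    The subtracted term is the receptor fraction held desensitized by the
    background concentration ``c0``; it is zero at rest (c_periph == c0).  If
    the perisynaptic concentration transiently dips below the background the
    raw difference turns negative, which would act as a negative conductance;
    by default the gate is clipped at 0 (with a warning, suppressible via
    ``warn=False``).
    """
    raw = s_nmda(c_periph, p) - s_nmda(c0, p)
    if clip:
        clipped = np.clip(raw, 0.0, None)
        if warn and np.any(np.asarray(raw) < 0):
            warnings.warn(
                "NMDA gate clipped at 0: perisynaptic glutamate dipped below background",
                RuntimeWarning,
                stacklevel=2,
            )
        raw = clipped
    arr = np.asarray(raw)
    return arr if arr.ndim else float(arr)
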