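"""Passive two-compartment neuron: current/voltage clamp, synaptic currents.

The cell is a soma (potential U) coupled to a lumped dendrite (U_d) through
the electrotonic parameters gamma (area ratio) and l (squared length ratio).
Synaptic receptors are dendritic, so by default both the driving force and the
magnesium block of the NMDA conductance are evaluated at U_d; a somatic
voltage clamp controls U but not U_d (the space-clamp problem), which is what
makes NMDA response amplitudes at -20 and +40 mV holding comparable despite
the very different nominal driving forces.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

from .params import NeuronParams, ParameterError, ReceptorParams

__all__ = [
    "ClampSpec",
    "mg_block_factor",
    "synaptic_currents",
    "cc_rhs",
    "input_conductance",
    "vc_rhs",
    "resting_vc",
    "somatic_current_vc",
    "reconstruct_dendritic_current",
    "one_compartment_rhs",
]

_MG_SCALE_MM = 3.57  # mM, magnesium block scale (Jahr-Stevens form)
_MG_SLOPE = 0.062  # 1/mV, voltage sensitivity of the block


@dataclass
class ClampSpec:
    """Recording configuration: clamp mode, holding potential, injected current.

    ``mode`` is ``"cc"`` (current clamp: inject I_inj, read V) or ``"vc"``
    (voltage clamp: hold the soma at V_h, read the clamp current).
    ``one_compartment`` collapses the cell to a single isopotential
    compartment receiving the synaptic current directly.
    """

    mode: str = "vc"
    V_h: float | None = None
    I_inj: Optional[Callable[[float], float]] = None
    one_compartment: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("cc", "vc"):
            raise ParameterError(f"clamp mode must be 'cc' or 'vc', got {self.mode!r}")
        if self.mode == "vc" and self.V_h is None:
            raise ParameterError("voltage clamp requires a holding potential V_h")
        if self.mode == "cc" and self.V_h is not None:
            raise ParameterError("V_h is only meaningful in voltage clamp")

    def injected(self, t: float) -> float:
        if self.I_inj is None:
            return 0.0
        return float(self.I_inj(t))


def mg_block_factor(V, mg_out: float):
    """Voltage-dependent magnesium unblock factor of the NMDA channel, in (0, 1].

    ``1 / (1 + ([Mg]o / 3.57 mM) * exp(-0.062 V))``; equals 1 with no
    magnesium, 1/2 at V = 0 when [Mg]o = 3.57 mM, and increases with
    depolarization.
    """
    if mg_out < 0:
        raise ValueError("mg_out must be non-negative")
    V = np.asarray(V, dtype=float)
    out = 1.0 / (1.0 + (mg_out / _MG_SCALE_MM) * np.exp(-_MG_SLOPE * V))
    return out if out.ndim else float(out)


def synaptic_currents(m_ampa, m_nmda, U_drive, p: ReceptorParams):
    """(I_AMPA, I_NMDA) in pA at the membrane potential seen by the receptors.

    ``I_AMPA = gbar * m * (U_rev - U_drive)``; the NMDA current carries the
    additional magnesium-block factor evaluated at the same potential.
    Currents are positive inward with this sign convention.
    """
    m_ampa = np.asarray(m_ampa, float)
    m_nmda = np.asarray(m_nmda, float)
    U_drive = np.asarray(U_drive, float)
    i_ampa = p.gbar_ampa * m_ampa * (p.U_ampa_rev - U_drive)
    i_nmda = (
        p.gbar_nmda
        * m_nmda
        * mg_block_factor(U_drive, p.mg_out)
        * (p.U_nmda_rev - U_drive)
    )
    if i_ampa.ndim == 0:
        return float(i_ampa), float(i_nmda)
    return i_ampa, i_nmda


def cc_rhs(U, U_d, I_d, I_inj, p: NeuronParams):
    """(dU/dt, dU_d/dt) in mV/ms for the current-clamped two-compartment cell.

    Soma: leak toward U_L, coupling (2 gamma / l)(U_d - U), injected current.
    Dendrite: leak, coupling -(2/l)(U_d - U), synaptic current I_d scaled by
    the dendritic conductance gamma * G_s.
    """
    if p.gamma == 0.0:
        if np.any(np.asarray(I_d, float) != 0.0):
            raise ParameterError("gamma = 0 (no dendrite) but a dendritic current was given")
        dU = (-(np.asarray(U, float) - p.U_L) + np.asarray(I_inj, float) / p.G_s) / p.tau_m
        return dU, np.zeros_like(np.asarray(U_d, float))
    U = np.asarray(U, float)
    U_d = np.asarray(U_d, float)
    dU = (
        -(U - p.U_L) + (2.0 * p.gamma / p.l) * (U_d - U) + np.asarray(I_inj, float) / p.G_s
    ) / p.tau_m
    dU_d = (
        -(U_d - p.U_L) - (2.0 / p.l) * (U_d - U) + np.asarray(I_d, float) / (p.gamma * p.G_s)
    ) / p.tau_m
    return dU, dU_d


def input_conductance(p: NeuronParams) -> float:
    """Somatic input conductance, closed form: ``G_s (3 + 2 gamma) / (3 + gamma)``.

    This is the conventional expression used to fix G_s from a measured input
    resistance before fitting.  Note it is independent of the electrotonic
    parameter l and therefore does not coincide with the steady state of the
    two-compartment equations themselves except at l = 2 gamma + 4; see
    :func:`input_conductance_from_equations` for the equation-consistent
    value.
    """
    return p.G_s * (3.0 + 2.0 * p.gamma) / (3.0 + p.gamma)


def input_conductance_from_equations(p: NeuronParams) -> float:
    """Input conductance implied by the steady state of the model equations.

    Solving the coupled somatic/dendritic equations for a constant somatic
    injection gives ``G_in = G_s (1 + 2 gamma / (l + 2))``.
    """
    return p.G_s * (1.0 + 2.0 * p.gamma / (p.l + 2.0))


def resting_vc(p: NeuronParams, V_h: float) -> float:
    """Resting dendritic potential under somatic voltage clamp at V_h.

    ``U_d0 = (U_L + 2 V_h / l) / (1 + 2 / l)`` — between the leak reversal and
    the holding potential, approaching U_L for an electrotonically long
    dendrite (large l).
    """
    return (p.U_L + 2.0 * V_h / p.l) / (1.0 + 2.0 / p.l)


def vc_rhs(U_d, I_d, V_h: float, p: NeuronParams):
    """dU_d/dt in voltage clamp: the dendritic equation with U fixed at V_h."""
    U_d = np.asarray(U_d, float)
    out = (
        -(U_d - p.U_L) - (2.0 / p.l) * (U_d - V_h) + np.asarray(I_d, float) / (p.gamma * p.G_s)
    ) / p.tau_m
    return out if out.ndim else float(out)


def somatic_current_vc(U_d, V_h: float, p: NeuronParams):
    """Somatically recorded clamp current: ``2 (G_s gamma / l) (U_d - U_d0)`` pA."""
    U_d = np.asarray(U_d, float)
    out = 2.0 * (p.G_s * p.gamma / p.l) * (U_d - resting_vc(p, V_h))
    return out if out.ndim else float(out)


def reconstruct_dendritic_current(
    i_vc: np.ndarray,
    dt: float,
    p: NeuronParams,
    smooth_window: int = 0,
) -> np.ndarray:
    """Reconstruct I_d(t) from a sampled somatic clamp current trace.

    Applies the first-order operator ``(l/2) tau_m d/dt + 1 + l/2`` with a
    second-order central finite difference (one-sided at the endpoints).  For
    the passive linear cable the operator inverts the clamp exactly; with
    sampled data it is approximate, so an optional moving-average smoothing of
    width ``smooth_window`` samples can precede differentiation.
    """
    i_vc = np.asarray(i_vc, dtype=float)
    if i_vc.ndim != 1 or i_vc.size < 3:
        raise ValueError("trace must be 1-D with at least 3 samples")
    if dt <= 0:
        raise ValueError("sampling interval must be positive")
    if smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        pad = smooth_window // 2
        padded = np.pad(i_vc, pad, mode="edge")
        i_vc = np.convolve(padded, kernel, mode="same")[pad : pad + len(np.atleast_1d(i_vc))]
    deriv = np.gradient(i_vc, dt, edge_order=2)
    return (p.l / 2.0) * p.tau_m * deriv + (1.0 + p.l / 2.0) * i_vc


def one_compartment_rhs(U, I_syn, I_inj, p: NeuronParams):
    """dU/dt for the single-compartment reduction (gamma -> 0, l -> 0).

    The cell collapses to one isopotential compartment receiving the synaptic
    current directly: ``tau_m dU/dt = -(U - U_L) + (I_syn + I_inj) / G_s``.
    """
    U = np.asarray(U, float)
    out = (-(U - p.U_L) + (np.asarray(I_syn, float) + np.asarray(I_inj, float)) / p.G_s) / p.tau_m
    return out if out.ndim else float(out)
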