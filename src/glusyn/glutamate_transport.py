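"""Two-compartment glutamate dynamics: release, diffusion, EAAT2 uptake.

Glutamate is released into the central synaptic cleft as square flux pulses,
exchanges with a perisynaptic compartment (volume ratio beta), leaks from
there toward the bulk/perfusate level c0, and is removed by astrocytic EAAT2
transporters acting on the perisynaptic compartment only — transporters are
essentially absent from the cleft itself.  Transporter blockade is modelled by
switching the uptake term off and raising the background concentration c0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import ParameterError, TransportParams

__all__ = [
    "StimulusTrain",
    "nu",
    "sodium_factor",
    "eaat2_flux",
    "cleft_rhs",
    "periph_rhs",
]


@dataclass
class StimulusTrain:
    """Square glutamate release pulses evoked by a train of stimuli.

    Each pulse delivers flux ``amplitude`` (uM/ms, the product W*nu^pulse)
    for ``duration`` ms starting at each onset; windows are half-open
    ``[onset, onset + duration)`` so the train is unambiguous at the edges.
    """

    pulse_onsets: tuple = ()
    amplitude: float = 200.0
    duration: float = 1.0

    def __post_init__(self) -> None:
        self.pulse_onsets = tuple(float(t) for t in self.pulse_onsets)
        if self.duration <= 0:
            raise ParameterError(f"pulse duration must be > 0, got {self.duration}")
        on = self.pulse_onsets
        if any(b <= a for a, b in zip(on, on[1:])):
            raise ParameterError("pulse onsets must be strictly increasing")
        if any(b - a < self.duration for a, b in zip(on, on[1:])):
            raise ParameterError("pulses overlap: inter-onset interval < duration")

    @classmethod
    def periodic(
        cls,
        n_pulses: int = 5,
        frequency_hz: float = 50.0,
        amplitude: float = 200.0,
        duration: float = 1.0,
        start: float = 10.0,
    ) -> "StimulusTrain":
        """Regular train; default is the 5-pulse 50 Hz stimulation protocol."""
        period_ms = 1000.0 / frequency_hz
        onsets = tuple(start + i * period_ms for i in range(n_pulses))
        return cls(onsets, amplitude, duration)

    @classmethod
    def empty(cls) -> "StimulusTrain":
        return cls(())

    def nu(self, t):
        """Release flux nu(t) in uM/ms (vectorized over t)."""
        t = np.asarray(t, dtype=float)
        on = np.zeros(t.shape, dtype=bool)
        for onset in self.pulse_onsets:
            on |= (t >= onset) & (t < onset + self.duration)
        out = np.where(on, self.amplitude, 0.0)
        return out if out.ndim else float(out)

    def edges(self, t_end: float):
        """Sorted pulse on/off times inside (0, t_end); integration steps on them."""
        e = []
        for onset in self.pulse_onsets:
            for x in (onset, onset + self.duration):
                if 0.0 < x < t_end:
                    e.append(x)
        return sorted(e)

    def total_release(self) -> float:
        """Total glutamate delivered by the train at F = 1, uM."""
        return len(self.pulse_onsets) * self.amplitude * self.duration


def nu(t, s: StimulusTrain):
    """Module-level alias for :meth:`StimulusTrain.nu`."""
    return s.nu(t)


def sodium_factor(gradient_mM, p: TransportParams):
    """Sodium-gradient factor of EAAT2 transport, in [0, 1).

    ``g**n / (na_half**n + g**n)`` with g the trans-membrane sodium gradient
    (mM); half-maximal at ``p.na_half``.  Under fixed sodium levels this is a
    run constant.
    """
    g = np.asarray(gradient_mM, dtype=float)
    if np.any(g < 0):
        raise ValueError("sodium gradient must be non-negative")
    gn = g ** p.na_exp
    out = gn / (p.na_half ** p.na_exp + gn)
    return out if out.ndim else float(out)


def eaat2_flux(c, p: TransportParams):
    """Normalized EAAT2 transport rate: sodium factor x Michaelis-Menten in glutamate.

    The glutamate factor ``c / (k_half_glu + c)`` is half-maximal at
    ``p.k_half_glu`` uM; the whole expression is monotone increasing in c and
    vanishes at c = 0.
    """
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("glutamate concentration must be non-negative")
    out = sodium_factor(p.na_ext - p.na_astro, p) * c / (p.k_half_glu + c)
    return out if out.ndim else float(out)


def cleft_rhs(c, c_periph, F, t, s: StimulusTrain, p: TransportParams):
    """dC_glu/dt (uM/ms) in the central cleft.

    Exchange with the perisynaptic compartment (time tau_glu) plus
    facilitation-scaled release ``F * nu(t)``; deliberately no uptake term —
    EAAT2 acts outside the cleft.
    """
    return (np.asarray(c_periph, float) - np.asarray(c, float)) / p.tau_glu + np.asarray(
        F, float
    ) * s.nu(t)


def periph_rhs(c, c_periph, p: TransportParams, uptake_on: bool = True, c0=None):
    """dC_glu^periph/dt (uM/ms) in the perisynaptic compartment.

    Back-diffusion from the cleft (slowed by the volume ratio beta), exchange
    with the bulk level c0 (time tau_diff), minus EAAT2 uptake when
    ``uptake_on``.  Transporter blockade == ``uptake_on=False`` (uptake rate
    zero) together with a nonzero c0.
    """
    if c0 is None:
        c0 = p.c0
    c = np.asarray(c, float)
    cp = np.asarray(c_periph, float)
    out = (c - cp) / (p.beta * p.tau_glu) - (cp - c0) / p.tau_diff
    if uptake_on:
        out = out - p.alpha_periph * eaat2_flux(cp, p)
    arr = np.asarray(out)
    return arr if arr.ndim else float(arr)
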