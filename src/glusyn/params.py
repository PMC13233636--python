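"""Parameter containers for the synaptic transmission model.

Units are normalized throughout the package: time in ms, potentials in mV,
conductances in nS (so conductance x potential = pA), glutamate concentrations
in uM, sodium concentrations in mM.  Published parameter tables often mix ms
and s; :func:`from_seconds` / :func:`per_second` convert at load time and the
config loader accepts explicit unit tags (see :mod:`glusyn.config`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace


def from_seconds(t_s: float) -> float:
    """Convert a time given in seconds to ms."""
    return 1000.0 * t_s


def seconds(t_ms: float) -> float:
    """Convert a time in ms back to seconds (round trip of :func:`from_seconds`)."""
    return t_ms / 1000.0


def per_second(r_per_s: float) -> float:
    """Convert a rate given in 1/s to 1/ms."""
    return r_per_s / 1000.0


def per_ms(r_per_ms: float) -> float:
    """Convert a rate in 1/ms back to 1/s."""
    return 1000.0 * r_per_ms


class ParameterError(ValueError):
    """Raised when a parameter set violates its domain constraints."""


@dataclass
class NeuronParams:
    """Electrotonic constants of the passive two-compartment pyramidal cell.

    Attributes
    ----------
    tau_m : float
        Membrane time constant, ms.
    gamma : float
        Dendrite/soma membrane area ratio (dimensionless).
    l : float
        Electrotonic parameter: squared ratio of dendrite length to the
        characteristic length (dimensionless).
    G_s : float
        Somatic leak conductance, nS.  Fixed per cell from the measured input
        conductance.
    U_L : float
        Leak reversal potential, mV (cell specific; Cs-based pipette solutions
        shift it strongly depolarized).
    """

    tau_m: float = 11.0
    gamma: float = 2.0
    l: float = 1.3
    G_s: float = 8.0
    U_L: float = -70.0

    def __post_init__(self) -> None:
        if self.tau_m <= 0:
            raise ParameterError(f"tau_m must be > 0, got {self.tau_m}")
        if self.G_s <= 0:
            raise ParameterError(f"G_s must be > 0, got {self.G_s}")
        if self.gamma < 0:
            raise ParameterError(f"gamma must be >= 0, got {self.gamma}")
        if self.l <= 0:
            raise ParameterError(f"l must be > 0, got {self.l}")


#: Per-cell somatic conductance (nS) and leak reversal (mV) of the four
#: reference cells used for fitting; the remaining parameters are shared.
CELL_SOMATIC_CONDUCTANCE = {1: 8.0, 2: 12.0, 3: 8.2, 4: 9.0}
CELL_LEAK_REVERSAL = {1: -70.0, 2: -69.0, 3: -34.0, 4: -4.0}


def neuron_params_for_cell(cell_id: int, **overrides) -> NeuronParams:
    """Neuron parameters with the per-cell fixed G_s and U_L filled in."""
    if cell_id not in CELL_SOMATIC_CONDUCTANCE:
        raise ParameterError(f"unknown cell id {cell_id!r}; known: 1..4")
    kw = dict(G_s=CELL_SOMATIC_CONDUCTANCE[cell_id], U_L=CELL_LEAK_REVERSAL[cell_id])
    kw.update(overrides)
    return NeuronParams(**kw)


@dataclass
class ReceptorParams:
    """AMPA/NMDA receptor gating, sensitivity and conductance parameters.

    The sensitivity curves are Hill functions of glutamate concentration with
    half-activation at ``ec50_ampa`` (Hill exponent ``hill_ampa``) and
    ``ec50_nmda`` (exponent 1); NMDA receptors are roughly 200x more sensitive
    to glutamate than AMPA receptors.

    tau_A is the AMPA receptor closing (deactivation) time in ms.  Conductance
    scales are in nS, reversal potentials in mV, external magnesium in mM.
    """

    tau_A: float = 2.0
    ec50_ampa: float = 1000.0
    hill_ampa: float = 1.6
    ec50_nmda: float = 4.7
    gbar_ampa: float = 3040.0
    gbar_nmda: float = 75.0
    U_ampa_rev: float = 0.0
    U_nmda_rev: float = 0.0
    mg_out: float = 1.0

    def __post_init__(self) -> None:
        if self.tau_A <= 0:
            raise ParameterError(f"tau_A must be > 0, got {self.tau_A}")
        if self.ec50_ampa <= 0 or self.ec50_nmda <= 0:
            raise ParameterError("receptor EC50 values must be > 0")
        if self.hill_ampa <= 0:
            raise ParameterError(f"hill_ampa must be > 0, got {self.hill_ampa}")
        if self.gbar_ampa < 0 or self.gbar_nmda < 0:
            raise ParameterError("conductance scales must be >= 0")
        if self.mg_out < 0:
            raise ParameterError(f"mg_out must be >= 0, got {self.mg_out}")


@dataclass
class TransportParams:
    """Glutamate release, two-compartment diffusion and EAAT2 uptake.

    Attributes
    ----------
    tau_glu : float
        Diffusion time from the cleft center to the perisynaptic compartment, ms.
    tau_diff : float
        Diffusion time from the perisynaptic space to the bulk/perfusate, ms.
    beta : float
        Perisynaptic/cleft volume ratio (dimensionless).
    c0 : float
        Background glutamate concentration, uM.  Zero with intact uptake;
        nonzero under transporter blockade.
    alpha_periph : float
        Maximum perisynaptic EAAT2 uptake rate, uM/ms.
    k_half_glu : float
        Glutamate concentration of half-maximal transport, uM.
    na_ext, na_astro : float
        Extracellular and astrocytic sodium, mM; uptake is driven by their
        gradient.
    na_half : float
        Sodium gradient of half-maximal transport, mM.
    na_exp : float
        Exponent of the sodium dependence (dimensionless).
    w_nu_pulse : float
        Release amplitude W*nu^pulse, uM/ms.  W and nu^pulse only ever appear
        as a product, so a single parameter is used.
    dt_pulse : float
        Square release pulse duration, ms.
    """

    tau_glu: float = 2.9
    tau_diff: float = 1170.0
    beta: float = 66.0
    c0: float = 2.0
    alpha_periph: float = 0.31
    k_half_glu: float = 28.0
    na_ext: float = 130.0
    na_astro: float = 15.0
    na_half: float = 50.0
    na_exp: float = 1.5
    w_nu_pulse: float = 200.0
    dt_pulse: float = 1.0

    def __post_init__(self) -> None:
        for name in ("tau_glu", "tau_diff", "dt_pulse"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")
        if self.beta <= 0:
            raise ParameterError(f"beta must be > 0, got {self.beta}")
        if self.alpha_periph < 0:
            raise ParameterError("alpha_periph must be >= 0")
        if self.c0 < 0:
            raise ParameterError("c0 must be >= 0")
        if self.na_ext <= self.na_astro:
            raise ParameterError("na_ext must exceed na_astro (uptake needs a gradient)")
        if self.k_half_glu <= 0 or self.na_half <= 0:
            raise ParameterError("half-max concentrations must be > 0")


@dataclass
class PlasticityParams:
    """Glutamate-driven facilitation F(t) and AMPA desensitization D(t).

    tau_F (ms) is the facilitation decay time; H_F (1/ms) scales its
    glutamate-driven growth; F0 is the resting release fraction.  tau_D (ms) is
    the recovery time from desensitization; H_D (1/ms, printed as 1.3 1/s in
    the source table) scales activity-dependent depletion.  k_half_glu is the
    concentration scale shared with the transporter model.
    """

    tau_F: float = 0.16
    H_F: float = 64.0
    F0: float = 0.42
    tau_D: float = 410.0
    H_D: float = per_second(1.3)
    k_half_glu: float = 28.0

    def __post_init__(self) -> None:
        if self.tau_F <= 0 or self.tau_D <= 0:
            raise ParameterError("plasticity time constants must be > 0")
        if not 0.0 < self.F0 <= 1.0:
            raise ParameterError(f"F0 must lie in (0, 1], got {self.F0}")
        if self.H_F < 0 or self.H_D < 0:
            raise ParameterError("H_F and H_D must be >= 0")
        if self.k_half_glu <= 0:
            raise ParameterError("k_half_glu must be > 0")


@dataclass
class ModelParams:
    """Aggregate parameter set for the full seven-ODE model.

    ``use_qss`` replaces the facilitation ODE by its quasi-steady state
    (reducing the system order by one; valid because tau_F is far below every
    other time scale).  ``drive_at_soma`` evaluates the synaptic driving force
    and the magnesium block at the somatic potential instead of the dendritic
    one (the literal reading of the current equations; off by default because
    the receptors are dendritic).
    """

    neuron: NeuronParams = field(default_factory=NeuronParams)
    receptor: ReceptorParams = field(default_factory=ReceptorParams)
    transport: TransportParams = field(default_factory=TransportParams)
    plasticity: PlasticityParams = field(default_factory=PlasticityParams)
    use_qss: bool = False
    drive_at_soma: bool = False

    def replace(self, **groups) -> "ModelParams":
        """Return a copy with whole sub-groups or flags replaced."""
        return replace(self, **groups)

    def with_values(self, values: dict) -> "ModelParams":
        """Return a copy with flat ``{name: value}`` overrides applied.

        Names are resolved through the fitting registry (e.g. ``tau_glu`` maps
        to ``transport.tau_glu``); unknown names raise ``ParameterError``.
        """
        from .fitting import PARAM_REGISTRY  # local import to avoid a cycle

        groups = {g: dict() for g in ("neuron", "receptor", "transport", "plasticity")}
        for name, value in values.items():
            if name not in PARAM_REGISTRY:
                raise ParameterError(f"unknown model parameter {name!r}")
            group, attr = PARAM_REGISTRY[name].group, PARAM_REGISTRY[name].attr
            groups[group][name if attr is None else attr] = value
        out = self
        for group, kw in groups.items():
            if kw:
                out = replace(out, **{group: replace(getattr(out, group), **kw)})
        return out

    def flat(self) -> dict:
        """All parameters as a flat ``{group.field: value}`` mapping (for logs)."""
        out = {}
        for group in ("neuron", "receptor", "transport", "plasticity"):
            obj = getattr(self, group)
            for f in fields(obj):
                out[f"{group}.{f.name}"] = getattr(obj, f.name)
        return out


def table_params(cell_id: int = 1, **neuron_overrides) -> ModelParams:
    """The reference parameter set with a given cell's fixed G_s and U_L."""
    return ModelParams(neuron=neuron_params_for_cell(cell_id, **neuron_overrides))
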