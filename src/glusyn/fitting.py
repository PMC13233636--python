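"""Staged least-squares fitting of model parameters to recorded traces.

The loss is the mean-squared error between simulated and recorded traces on
the recording's own time grid, summed (optionally weighted) over traces.
Minimization uses the Nelder-Mead downhill simplex on transformed parameters
— log for positive quantities (times, rates, conductances), logit for
fractions — which keeps the search in the physical domain without explicit
bound handling.

The staged schedule mirrors how such datasets are fitted in practice: the
passive neuron parameters first (reproducing the current-clamp voltage from
the reconstructed dendritic current), then AMPA-dominated traces, then NMDA
traces, then a joint refinement over everything, each stage warm-starting
from the previous.  Robustness is probed by restarting the whole schedule
from randomly perturbed parameter values and reporting the dispersion of the
recovered optima.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Optional

import numpy as np
from scipy.optimize import minimize

from .glutamate_transport import StimulusTrain
from .neuron_electrotonics import ClampSpec, reconstruct_dendritic_current
from .params import ModelParams, ParameterError
from .simulator import Condition, SolverOptions, resting_state, simulate

__all__ = [
    "ParamDef",
    "PARAM_REGISTRY",
    "FitTarget",
    "FitStage",
    "FitSpec",
    "FitResult",
    "mse_loss",
    "fit_stage",
    "staged_fit",
    "perturb_and_recover",
    "simulate_cc_from_vc",
]


@dataclass(frozen=True)
class ParamDef:
    """A fittable parameter: its group, attribute name, and transform."""

    group: str
    transform: str = "log"  # "log" for positive, "logit" for (0, 1)
    attr: Optional[str] = None  # defaults to the registry key


def _registry() -> dict:
    reg = {
        "tau_m": ParamDef("neuron"),
        "gamma": ParamDef("neuron"),
        "l": ParamDef("neuron"),
        "G_s": ParamDef("neuron"),
        "tau_A": ParamDef("receptor"),
        "gbar_ampa": ParamDef("receptor"),
        "gbar_nmda": ParamDef("receptor"),
        "ec50_ampa": ParamDef("receptor"),
        "ec50_nmda": ParamDef("receptor"),
        "hill_ampa": ParamDef("receptor"),
        "mg_out": ParamDef("receptor"),
        "tau_glu": ParamDef("transport"),
        "tau_diff": ParamDef("transport"),
        "beta": ParamDef("transport"),
        "alpha_periph": ParamDef("transport"),
        "c0": ParamDef("transport"),
        "k_half_glu": ParamDef("transport"),
        "w_nu_pulse": ParamDef("transport"),
        "tau_F": ParamDef("plasticity"),
        "H_F": ParamDef("plasticity"),
        "F0": ParamDef("plasticity", transform="logit"),
        "tau_D": ParamDef("plasticity"),
        "H_D": ParamDef("plasticity"),
    }
    return reg


#: Flat name -> location/transform registry for every fittable parameter.
PARAM_REGISTRY = _registry()


def _to_internal(name: str, value: float) -> float:
    tf = PARAM_REGISTRY[name].transform
    if tf == "log":
        if value <= 0:
            raise ParameterError(f"{name} must be positive for the log transform")
        return math.log(value)
    if tf == "logit":
        if not 0.0 < value < 1.0:
            raise ParameterError(f"{name} must lie in (0,1) for the logit transform")
        return math.log(value / (1.0 - value))
    raise ParameterError(f"unknown transform {tf!r}")


def _from_internal(name: str, x: float) -> float:
    tf = PARAM_REGISTRY[name].transform
    if tf == "log":
        return math.exp(x)
    return 1.0 / (1.0 + math.exp(-x))


@dataclass
class FitTarget:
    """One trace to fit: the data, its protocol and recording configuration.

    ``kind`` selects the forward model: ``"trace"`` simulates the full model
    and compares the recorded observable (clamp current or voltage);
    ``"cc_from_vc"`` drives the passive two-compartment cell with the
    dendritic current reconstructed from ``source_trace`` (a somatic VC
    recording) and compares the resulting somatic voltage — the first fitting
    stage of the pipeline.
    """

    time: np.ndarray
    values: np.ndarray
    protocol: StimulusTrain
    clamp: ClampSpec
    condition: Condition
    cell_params: dict = field(default_factory=dict)  # fixed per-cell values (G_s, U_L)
    isolation: str = "mixed"  # "ampa" | "nmda" | "mixed"
    weight: float = 1.0
    tags: tuple = ()
    kind: str = "trace"
    source_trace: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.time.shape != self.values.shape:
            raise ParameterError("time and value arrays must have the same shape")
        if self.kind == "cc_from_vc" and self.source_trace is None:
            raise ParameterError("cc_from_vc target needs the source VC trace")


@dataclass
class FitStage:
    """A stage of the schedule: which parameters move against which targets."""

    name: str
    free: tuple
    target_tags: Optional[tuple] = None  # None = all targets
    maxfev: Optional[int] = None


@dataclass
class FitSpec:
    """Targets, free parameters with initial values, and the stage schedule."""

    targets: list
    initial: dict
    stages: list
    base_params: ModelParams = field(default_factory=ModelParams)
    solver: SolverOptions = SolverOptions(rtol=1e-6, atol=1e-9, dt=1.0)
    baseline_subtract: bool = True

    def __post_init__(self) -> None:
        seen = {}
        for st in self.stages:
            for p in st.free:
                if p not in PARAM_REGISTRY:
                    raise ParameterError(f"unknown fit parameter {p!r}")
                seen.setdefault(p, []).append(st.name)
        for p in self.initial:
            if p not in PARAM_REGISTRY:
                raise ParameterError(f"unknown fit parameter {p!r}")


@dataclass
class FitResult:
    """Outcome of a staged fit."""

    values: dict
    loss: float
    initial_loss: float
    stage_history: list  # (stage name, loss after stage, nfev)
    success: bool
    flags: list

    def __post_init__(self) -> None:
        assert self.loss <= self.initial_loss + 1e-12, "fit must not increase the loss"


def mse_loss(sim: np.ndarray, data: np.ndarray, weight: float = 1.0) -> float:
    """Mean squared pointwise difference of two traces on a shared grid."""
    sim = np.asarray(sim, float)
    data = np.asarray(data, float)
    if sim.shape != data.shape:
        raise ValueError(f"trace grids differ after resampling: {sim.shape} vs {data.shape}")
    return float(weight * np.mean((sim - data) ** 2))


def simulate_cc_from_vc(
    i_vc: np.ndarray, time: np.ndarray, params: ModelParams
) -> np.ndarray:
    """Somatic voltage of the passive cell driven by the reconstructed I_d.

    Reconstructs the dendritic current from a somatic VC trace, then
    integrates the passive current-clamp equations with that current
    interpolated onto the solver's time points.  Used by the neuron stage of
    the fit, where the CC recording is reproduced from the VC recording.
    """
    from scipy.integrate import solve_ivp

    n = params.neuron
    dt = float(time[1] - time[0])
    i_d = reconstruct_dendritic_current(np.asarray(i_vc, float), dt, n)
    t = np.asarray(time, float)

    def rhs(tt, y):
        U, U_d = y
        cur = np.interp(tt, t, i_d)
        dU = (-(U - n.U_L) + (2.0 * n.gamma / n.l) * (U_d - U)) / n.tau_m
        dU_d = (-(U_d - n.U_L) - (2.0 / n.l) * (U_d - U) + cur / (n.gamma * n.G_s)) / n.tau_m
        return (dU, dU_d)

    sol = solve_ivp(rhs, (t[0], t[-1]), (n.U_L, n.U_L), method="LSODA", t_eval=t,
                    rtol=1e-8, atol=1e-10)
    if not sol.success:
        raise RuntimeError(f"passive CC integration failed: {sol.message}")
    return sol.y[0]


def _apply_isolation(params: ModelParams, isolation: str) -> ModelParams:
    """Pharmacological receptor isolation: zero the blocked conductance."""
    if isolation == "ampa":
        return params.replace(receptor=replace(params.receptor, gbar_nmda=0.0))
    if isolation == "nmda":
        return params.replace(receptor=replace(params.receptor, gbar_ampa=0.0))
    return params


def _target_params(spec: FitSpec, target: FitTarget, values: dict) -> ModelParams:
    p = spec.base_params.with_values(values)
    if target.cell_params:
        p = p.with_values(
            {k: v for k, v in target.cell_params.items() if k in PARAM_REGISTRY}
        )
        extra = {k: v for k, v in target.cell_params.items() if k not in PARAM_REGISTRY}
        if extra:  # U_L and other direct neuron fields are not fit parameters
            p = p.replace(neuron=replace(p.neuron, **extra))
    return _apply_isolation(p, target.isolation)


def _predict(spec: FitSpec, target: FitTarget, values: dict) -> np.ndarray:
    p = _target_params(spec, target, values)
    if target.kind == "cc_from_vc":
        return simulate_cc_from_vc(target.source_trace, target.time, p)
    t_end = float(target.time[-1])
    dt = float(target.time[1] - target.time[0])
    solver = replace(spec.solver, dt=dt)
    res = simulate(p, target.protocol, target.clamp, target.condition, t_end, solver)
    sim = np.interp(target.time, res.time, res.recorded)
    return sim


def _baseline(target: FitTarget, trace: np.ndarray) -> np.ndarray:
    onset = target.protocol.pulse_onsets[0] if target.protocol.pulse_onsets else None
    if onset is None:
        return trace
    pre = target.time < onset
    if not np.any(pre):
        return trace
    return trace - trace[pre].mean()


def total_loss(spec: FitSpec, values: dict, targets: Optional[list] = None) -> float:
    """Weighted sum of per-trace MSE losses at the given parameter values."""
    targets = spec.targets if targets is None else targets
    loss = 0.0
    for tgt in targets:
        sim = _predict(spec, tgt, values)
        data = tgt.values
        if spec.baseline_subtract:
            sim = _baseline(tgt, sim)
            data = _baseline(tgt, data)
        loss += mse_loss(sim, data, tgt.weight)
    return loss


def _stage_targets(spec: FitSpec, stage: FitStage) -> list:
    if stage.target_tags is None:
        return spec.targets
    sel = [t for t in spec.targets if set(stage.target_tags) & set(t.tags)]
    if not sel:
        raise ParameterError(f"stage {stage.name!r} matches no targets")
    return sel


def fit_stage(
    spec: FitSpec,
    stage: FitStage,
    values: Optional[dict] = None,
    maxfev: Optional[int] = None,
) -> "FitResult":
    """Nelder-Mead minimization of one stage's parameters on its targets.

    Returns a FitResult whose ``values`` merge the optimized stage parameters
    into the incoming values; parameters outside the stage stay fixed.  A
    stage whose loss surface is flat (no improvement and negligible gradient
    across the simplex) is flagged rather than failed.
    """
    values = dict(spec.initial if values is None else values)
    targets = _stage_targets(spec, stage)
    free = list(stage.free)
    x0 = np.array([_to_internal(p, values[p]) for p in free])

    def objective(x):
        trial = dict(values)
        for p, xi in zip(free, x):
            trial[p] = _from_internal(p, xi)
        return total_loss(spec, trial, targets)

    f0 = objective(x0)
    maxfev = maxfev or stage.maxfev or 200 * len(free)
    opt = minimize(
        objective,
        x0,
        method="Nelder-Mead",
        options={"maxfev": maxfev, "xatol": 1e-4, "fatol": 1e-12, "adaptive": len(free) > 4},
    )
    flags = []
    best_x, best_f = (opt.x, opt.fun) if opt.fun <= f0 else (x0, f0)
    if not opt.success:
        flags.append(f"stage {stage.name}: {opt.message} (best-so-far returned)")
    if f0 > 0 and (f0 - best_f) / f0 < 1e-12:
        flags.append(f"stage {stage.name}: flat loss landscape, no sensitive parameters")
    out = dict(values)
    for p, xi in zip(free, best_x):
        out[p] = _from_internal(p, xi)
    # loss fields refer to this stage's own targets; the schedule-level result
    # of staged_fit reports the loss over all targets
    return FitResult(
        values=out,
        loss=float(best_f),
        initial_loss=float(f0),
        stage_history=[(stage.name, float(best_f), int(opt.nfev))],
        success=opt.success,
        flags=flags,
    )


def staged_fit(spec: FitSpec, values: Optional[dict] = None) -> FitResult:
    """Run the full stage schedule, each stage warm-starting from the last."""
    values = dict(spec.initial if values is None else values)
    initial_loss = total_loss(spec, values)
    history, flags = [], []
    ok = True
    for stage in spec.stages:
        r = fit_stage(spec, stage, values)
        values = r.values
        history.extend(r.stage_history)
        flags.extend(r.flags)
        ok = ok and r.success
    final = total_loss(spec, values)
    if final > initial_loss:  # never report an uphill move
        final = initial_loss
        values = dict(spec.initial)
        flags.append("schedule failed to improve; initial values returned")
    return FitResult(values, final, initial_loss, history, ok, flags)


def default_fit_spec(
    recordings: dict,
    base_params: Optional[ModelParams] = None,
    free: Optional[list] = None,
    maxfev: Optional[int] = None,
    use_qss: bool = True,
) -> FitSpec:
    """The standard four-stage FitSpec for a generated recording dataset.

    Stage 1 (neuron) fits the passive electrotonic parameters by reproducing
    the cell-1 current-clamp voltage from the dendritic current reconstructed
    out of the matching voltage-clamp trace; stage 2 fits the AMPA-dominated
    traces; stage 3 the NMDA traces; stage 4 refines everything jointly.
    Stages whose traces are absent from ``recordings`` are dropped.  ``free``
    restricts the fitted parameters (the neuron stage is dropped if none of
    its parameters remain free).
    """
    from .params import CELL_LEAK_REVERSAL, CELL_SOMATIC_CONDUCTANCE

    base = ModelParams() if base_params is None else base_params
    if use_qss:
        base = base.replace(use_qss=True)
    train = StimulusTrain.periodic(
        amplitude=base.transport.w_nu_pulse, duration=base.transport.dt_pulse
    )
    targets = []
    vc_source = recordings.get("cell1_mixed_vc_control")
    cc_rec = recordings.get("cell1_mixed_cc_control")
    if vc_source is not None and cc_rec is not None:
        targets.append(
            FitTarget(
                time=cc_rec.time,
                values=cc_rec.values,
                protocol=train,
                clamp=ClampSpec(mode="cc"),
                condition=Condition.control(),
                cell_params={"G_s": CELL_SOMATIC_CONDUCTANCE[1], "U_L": CELL_LEAK_REVERSAL[1]},
                isolation="mixed",
                tags=("neuron",),
                kind="cc_from_vc",
                source_trace=vc_source.values,
            )
        )
    for key, rec in recordings.items():
        if rec.mode != "vc" or rec.isolation == "mixed":
            continue
        targets.append(
            FitTarget(
                time=rec.time,
                values=rec.values,
                protocol=train,
                clamp=ClampSpec(mode="vc", V_h=float(rec.v_hold)),
                condition=Condition.control() if rec.condition == "control"
                else Condition.blockade(base.transport.c0),
                cell_params={
                    "G_s": CELL_SOMATIC_CONDUCTANCE.get(rec.cell_id, base.neuron.G_s),
                    "U_L": CELL_LEAK_REVERSAL.get(rec.cell_id, base.neuron.U_L),
                },
                isolation=rec.isolation,
                tags=(rec.isolation,),
            )
        )
    if not targets:
        raise ParameterError("no usable recordings for fitting")

    default_free = {
        "neuron": ("tau_m", "gamma", "l"),
        "ampa": ("gbar_ampa", "tau_A", "tau_glu"),
        "nmda": ("gbar_nmda", "tau_diff", "beta", "alpha_periph"),
    }
    if free is not None:
        default_free = {
            k: tuple(p for p in v if p in free) for k, v in default_free.items()
        }
    all_free = tuple(dict.fromkeys(p for v in default_free.values() for p in v))
    have = {tag for t in targets for tag in t.tags}
    stages = []
    for name in ("neuron", "ampa", "nmda"):
        if name in have and default_free[name]:
            stages.append(FitStage(name, default_free[name], target_tags=(name,), maxfev=maxfev))
    stages.append(FitStage("joint", all_free, target_tags=None, maxfev=maxfev))
    initial = {p: _current_value(base, p) for p in all_free}
    return FitSpec(targets=targets, initial=initial, stages=stages, base_params=base)


def _current_value(params: ModelParams, name: str) -> float:
    d = PARAM_REGISTRY[name]
    return getattr(getattr(params, d.group), d.attr or name)


def perturb_and_recover(
    spec: FitSpec,
    n_restarts: int = 5,
    dispersion: float = 0.5,
    seed: int = 0,
    reference: Optional[dict] = None,
) -> dict:
    """Restart the staged fit from uniformly perturbed initial values.

    Each restart multiplies every free parameter of ``reference`` (default:
    the spec's initial values) by ``1 + U(-dispersion, +dispersion)`` and runs
    the schedule.  Returns per-parameter maximum relative deviation of the
    recovered values from the reference, the overall maximum, and all fit
    results.  Deterministic for a fixed seed.
    """
    if n_restarts < 1:
        raise ParameterError("n_restarts must be >= 1")
    reference = dict(spec.initial if reference is None else reference)
    rng = np.random.default_rng(seed)
    names = sorted({p for st in spec.stages for p in st.free})
    results = []
    per_param = {p: 0.0 for p in names}
    for _ in range(n_restarts):
        start = dict(reference)
        factors = 1.0 + rng.uniform(-dispersion, dispersion, size=len(names))
        for p, f in zip(names, factors):
            start[p] = reference[p] * f
        r = staged_fit(spec, start)
        results.append(r)
        for p in names:
            dev = abs(r.values[p] - reference[p]) / abs(reference[p])
            per_param[p] = max(per_param[p], dev)
    return {
        "per_param_max_rel_dev": per_param,
        "max_rel_dev": max(per_param.values()) if per_param else 0.0,
        "n_restarts": n_restarts,
        "dispersion": dispersion,
        "results": results,
    }
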