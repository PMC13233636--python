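"""YAML configuration loading with unit normalization.

A config file has sections mirroring the parameter groups (``neuron``,
``receptor``, ``transport``, ``plasticity``), a ``protocol`` section for the
stimulus train, a ``clamp`` section and optional ``condition``/``solver``
sections.  A scalar entry is taken in the package's native units (ms-based);
an entry written as ``{value: 1.17, unit: s}`` is converted at load time.
Recognized units: ms, s, per_ms, per_s (and 1/ms, 1/s aliases).
"""

from __future__ import annotations

from dataclasses import fields
from pathlib import Path

import yaml

from .glutamate_transport import StimulusTrain
from .neuron_electrotonics import ClampSpec
from .params import (
    ModelParams,
    NeuronParams,
    ParameterError,
    PlasticityParams,
    ReceptorParams,
    TransportParams,
    from_seconds,
    per_second,
)
from .simulator import Condition, SolverOptions

__all__ = ["load_config", "normalize_value", "build_model_params"]

_UNIT_CONVERT = {
    "ms": lambda v: v,
    "mv": lambda v: v,
    "ns": lambda v: v,
    "um": lambda v: v,
    "mm": lambda v: v,
    "s": from_seconds,
    "per_ms": lambda v: v,
    "1/ms": lambda v: v,
    "per_s": per_second,
    "1/s": per_second,
}


def normalize_value(entry):
    """Convert a config entry (scalar or {value, unit}) to native units."""
    if isinstance(entry, dict):
        if set(entry) != {"value", "unit"}:
            raise ParameterError(f"expected {{value, unit}} mapping, got {entry!r}")
        unit = str(entry["unit"]).lower()
        if unit not in _UNIT_CONVERT:
            raise ParameterError(f"unknown unit {entry['unit']!r}")
        return _UNIT_CONVERT[unit](float(entry["value"]))
    return entry


_GROUPS = {
    "neuron": NeuronParams,
    "receptor": ReceptorParams,
    "transport": TransportParams,
    "plasticity": PlasticityParams,
}


def _build_group(cls, section: dict):
    known = {f.name for f in fields(cls)}
    kw = {}
    for key, entry in section.items():
        if key not in known:
            raise ParameterError(f"unknown key {key!r} in {cls.__name__} section")
        kw[key] = normalize_value(entry)
    return cls(**kw)


def build_model_params(cfg: dict) -> ModelParams:
    groups = {name: _build_group(cls, cfg.get(name, {}) or {}) for name, cls in _GROUPS.items()}
    flags = cfg.get("model", {}) or {}
    unknown = set(flags) - {"use_qss", "drive_at_soma"}
    if unknown:
        raise ParameterError(f"unknown model flags: {sorted(unknown)}")
    return ModelParams(**groups, **flags)


def load_config(path):
    """Load a config file into (ModelParams, StimulusTrain, ClampSpec, Condition, SolverOptions)."""
    cfg = yaml.safe_load(Path(path).read_text()) or {}
    known = {"neuron", "receptor", "transport", "plasticity", "model", "protocol",
             "clamp", "condition", "solver"}
    unknown = set(cfg) - known
    if unknown:
        raise ParameterError(f"unknown config sections: {sorted(unknown)}")
    params = build_model_params(cfg)

    proto = cfg.get("protocol", {}) or {}
    unknown = set(proto) - {"n_pulses", "frequency_hz", "amplitude", "duration", "start"}
    if unknown:
        raise ParameterError(f"unknown protocol keys: {sorted(unknown)}")
    train = StimulusTrain.periodic(
        n_pulses=int(proto.get("n_pulses", 5)),
        frequency_hz=float(normalize_value(proto.get("frequency_hz", 50.0))),
        amplitude=float(normalize_value(proto.get("amplitude", params.transport.w_nu_pulse))),
        duration=float(normalize_value(proto.get("duration", params.transport.dt_pulse))),
        start=float(normalize_value(proto.get("start", 10.0))),
    )

    cl = cfg.get("clamp", {}) or {}
    unknown = set(cl) - {"mode", "V_h", "one_compartment"}
    if unknown:
        raise ParameterError(f"unknown clamp keys: {sorted(unknown)}")
    clamp = ClampSpec(
        mode=cl.get("mode", "vc"),
        V_h=cl.get("V_h", -70.0 if cl.get("mode", "vc") == "vc" else None),
        one_compartment=bool(cl.get("one_compartment", False)),
    )

    co = cfg.get("condition", {}) or {}
    label = co.get("label", "control")
    if label == "control":
        cond = Condition.control()
    elif label == "tboa":
        cond = Condition.blockade(float(co.get("c0", params.transport.c0)))
    else:
        raise ParameterError(f"condition label must be 'control' or 'tboa', got {label!r}")

    so = cfg.get("solver", {}) or {}
    unknown = set(so) - {"rtol", "atol", "max_step_pulse", "dt", "method"}
    if unknown:
        raise ParameterError(f"unknown solver keys: {sorted(unknown)}")
    solver = SolverOptions(**{k: (v if k == "method" else float(v)) for k, v in so.items()})

    return params, train, clamp, cond, solver
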