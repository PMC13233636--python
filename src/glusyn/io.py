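"""Trace I/O: delimited text recordings with commented metadata headers.

A recording is stored as plain text: ``#``-prefixed ``key = value`` metadata
lines followed by a one-line column header and two tab-separated columns
(time in ms, value in pA or mV).  Values are written with 17 significant
digits so the round trip is lossless for float64.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

__all__ = ["Recording", "read_trace", "write_trace"]

_META_FIELDS = ("cell_id", "mode", "v_hold", "condition", "isolation", "units", "noise_sigma", "seed")


@dataclass
class Recording:
    """A uniformly sampled current or voltage trace with its metadata."""

    time: np.ndarray
    values: np.ndarray
    cell_id: int = 0
    mode: str = "vc"  # "vc" | "cc"
    v_hold: Optional[float] = None
    condition: str = "control"  # "control" | "tboa"
    isolation: str = "mixed"  # "ampa" | "nmda" | "mixed"
    units: str = "pA"
    noise_sigma: float = 0.0
    seed: Optional[int] = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.time.ndim != 1 or self.time.shape != self.values.shape:
            raise ValueError("time and value columns must be 1-D and equal length")
        if self.time.size >= 2:
            d = np.diff(self.time)
            if np.any(d <= 0):
                raise ValueError("time column must be strictly increasing")
            if not np.allclose(d, d[0], rtol=1e-9, atol=1e-9):
                raise ValueError("time column must be uniformly sampled")

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])

    def label(self) -> str:
        vh = "" if self.v_hold is None else f"{self.v_hold:+.0f}mV_"
        return f"cell{self.cell_id}_{self.isolation}_{vh}{self.condition}"


def _fmt_meta(value):
    if value is None:
        return "none"
    return repr(value) if isinstance(value, float) else str(value)


def _parse_meta(raw: str):
    if raw == "none":
        return None
    for cast in (int, float):
        try:
            return cast(raw)
        except ValueError:
            continue
    return raw


def write_trace(rec: Recording, path) -> None:
    """Write a recording as delimited text with a commented metadata header."""
    path = Path(path)
    lines = [f"# {k} = {_fmt_meta(getattr(rec, k))}" for k in _META_FIELDS]
    lines += [f"# extra.{k} = {_fmt_meta(v)}" for k, v in sorted(rec.extra.items())]
    lines.append("time_ms\tvalue")
    body = "\n".join(
        f"{t:.17g}\t{v:.17g}" for t, v in zip(rec.time, rec.values)
    )
    path.write_text("\n".join(lines) + "\n" + body + "\n")


def read_trace(path) -> Recording:
    """Read a recording written by :func:`write_trace` (lossless round trip)."""
    path = Path(path)
    meta, extra = {}, {}
    times, values = [], []
    header_seen = False
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if "=" not in body:
                raise ValueError(f"{path}:{lineno}: malformed metadata line {line!r}")
            key, _, raw = (s.strip() for s in body.partition("="))
            if key.startswith("extra."):
                extra[key[6:]] = _parse_meta(raw)
            else:
                meta[key] = _parse_meta(raw)
            continue
        if not header_seen:
            cols = line.split("\t")
            if len(cols) < 2 or cols[0] != "time_ms":
                raise ValueError(
                    f"{path}:{lineno}: expected header 'time_ms\\tvalue', got {line!r}"
                )
            if "value" not in cols:
                raise ValueError(f"{path}:{lineno}: missing 'value' column")
            header_seen = True
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValueError(f"{path}:{lineno}: missing value column")
        times.append(float(parts[0]))
        values.append(float(parts[1]))
    if not header_seen:
        raise ValueError(f"{path}: no column header found")
    kwargs = {k: meta.get(k) for k in _META_FIELDS if k in meta}
    if kwargs.get("noise_sigma") is None:
        kwargs["noise_sigma"] = 0.0
    if kwargs.get("cell_id") is None:
        kwargs["cell_id"] = 0
    return Recording(np.array(times), np.array(values), extra=extra, **kwargs)
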