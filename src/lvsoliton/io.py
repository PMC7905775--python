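"""Configuration parsing and bit-exact JSON serialization.

All rationals cross the process boundary as ``"p/q"`` strings, never
floats, so that parse(emit(x)) == x holds bit-exactly.  Reports are
emitted with sorted keys: identical inputs produce byte-identical files.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from .exact import to_exact
from .solution import SolitarySolutionSet, evaluate_solution

__all__ = [
    "RunConfig",
    "ConfigError",
    "parse_config",
    "load_json",
    "emit_report",
    "export_trajectory",
]


class ConfigError(ValueError):
    """A configuration violates its schema; the message names the key."""


#: Allowed top-level keys per command configuration.
_SCHEMAS = {
    "kink": {"required": {"c0", "c1", "c2"}, "optional": {"x_init", "t_init"}},
    "pair-check": {"required": {"a0", "a1", "a2", "a3", "b0", "b1", "b2", "b3"},
                   "optional": set()},
    "construct": {"required": {"order", "free", "aes", "sigmas", "eta", "t0"},
                  "optional": {"zero_aes", "branch", "real_mode"}},
    "invert": {"required": {"order"}, "optional": {"gauge", "zero_aes"}},
    "fixture": {"required": {"order", "seed"}, "optional": {"magnitude"}},
}

_EXACT_KEYS = {"c0", "c1", "c2", "a0", "a1", "a2", "a3", "b0", "b1", "b2", "b3",
               "x_init", "t_init", "eta", "t0"}
_INT_KEYS = {"order", "seed", "branch", "magnitude"}


@dataclass(frozen=True)
class RunConfig:
    """A validated command configuration with exact scalars parsed."""

    command: str
    values: dict = field(default_factory=dict)

    def __getitem__(self, key):
        return self.values[key]

    def get(self, key, default=None):
        return self.values.get(key, default)


def _parse_value(key: str, raw):
    if isinstance(raw, float):
        raise ConfigError(
            f"key {key!r}: float literal {raw!r} is not exact; quote it as 'p/q'")
    if key in _INT_KEYS:
        if not isinstance(raw, int):
            raise ConfigError(f"key {key!r}: expected an integer")
        return raw
    if key in _EXACT_KEYS:
        try:
            return to_exact(raw)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"key {key!r}: {exc}") from exc
    if key in ("free", "sigmas", "gauge"):
        if not isinstance(raw, dict):
            raise ConfigError(f"key {key!r}: expected a mapping of exact rationals")
        out = {}
        for name, value in raw.items():
            if isinstance(value, float):
                raise ConfigError(
                    f"key {key}.{name}: float literal is not exact; quote it as 'p/q'")
            try:
                out[name] = to_exact(value)
            except (TypeError, ValueError) as exc:
                raise ConfigError(f"key {key}.{name}: {exc}") from exc
        return out
    if key == "aes":
        if not isinstance(raw, list):
            raise ConfigError("key 'aes': expected a list of exact rationals")
        return [to_exact(v) for v in raw]
    if key == "zero_aes":
        if not isinstance(raw, list) or not all(isinstance(v, int) for v in raw):
            raise ConfigError("key 'zero_aes': expected a list of integers")
        return raw
    if key == "real_mode":
        if not isinstance(raw, bool):
            raise ConfigError("key 'real_mode': expected a boolean")
        return raw
    raise ConfigError(f"unknown key {key!r}")


def parse_config(path, command: str) -> RunConfig:
    """Load and validate a JSON config for ``command``.

    Unknown keys are rejected; every scalar must be an exact rational
    (``"p/q"`` string or integer).  Schema defaults are applied.
    """
    schema = _SCHEMAS[command]
    with open(path) as handle:
        try:
            raw = json.load(handle)
        except json.JSONDecodeError as exc:
            raise ConfigError(f"invalid JSON in {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError("top-level config must be a JSON object")
    allowed = schema["required"] | schema["optional"]
    unknown = set(raw) - allowed
    if unknown:
        raise ConfigError(f"unknown keys: {sorted(unknown)}")
    missing = schema["required"] - set(raw)
    if missing:
        raise ConfigError(f"missing required keys: {sorted(missing)}")
    values = {key: _parse_value(key, value) for key, value in raw.items()}
    if "eta" in values and values["eta"] == 0:
        raise ConfigError("key 'eta': must be nonzero")
    return RunConfig(command=command, values=values)


def load_json(path) -> dict:
    with open(path) as handle:
        return json.load(handle)


def emit_report(result: Mapping, path: Optional[str] = None) -> str:
    """Serialize a report deterministically (sorted keys, fixed separators)."""
    text = json.dumps(result, sort_keys=True, indent=2, separators=(",", ": "))
    text += "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


def export_trajectory(sol: SolitarySolutionSet, t_start: float, t_end: float,
                      path, n_points: int = 401) -> None:
    """Closed-form trajectory as CSV with header t,x1,y1,x2,y2."""
    grid = np.linspace(float(t_start), float(t_end), n_points)
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(["t", "x1", "y1", "x2", "y2"])
        for t in grid:
            writer.writerow([repr(float(t))] + [repr(v) for v in evaluate_solution(sol, t)])
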