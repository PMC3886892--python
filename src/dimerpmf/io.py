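"""Flat key-value configuration dialect shared by all tools.

Syntax: one ``key = value`` per line, ``#`` comments, and
``include other.cfg`` lines (paths relative to the including file).
Values are parsed as int, float, tuple of numbers (comma separated) or
string, in that order of preference.  The same dialect is echoed into
result-file headers for provenance.
"""

from __future__ import annotations

import os

from .driver import ExperimentPlan
from .toygen import ToyConfig

__all__ = ["parse_config", "parse_value", "plan_from_mapping", "config_from_mapping"]


def parse_value(raw: str):
    raw = raw.strip()
    if "," in raw:
        try:
            return tuple(parse_value(p) for p in raw.split(","))
        except ValueError:
            return raw
    for cast in (int, float):
        try:
            return cast(raw)
        except ValueError:
            continue
    if raw.lower() in ("true", "false"):
        return raw.lower() == "true"
    return raw


def parse_config(path) -> dict:
    out: dict = {}
    base = os.path.dirname(os.path.abspath(path))
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if line.startswith("include "):
                inc = line.split(None, 1)[1].strip()
                out.update(parse_config(os.path.join(base, inc)))
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value', got {line!r}")
            key, raw = line.split("=", 1)
            out[key.strip()] = parse_value(raw)
    return out


def config_from_mapping(mapping: dict) -> ToyConfig:
    fields = {f for f in ToyConfig.__dataclass_fields__}
    kw = {k: v for k, v in mapping.items() if k in fields}
    return ToyConfig(**kw)


def plan_from_mapping(mapping: dict) -> ExperimentPlan:
    toy = config_from_mapping(mapping)
    fields = set(ExperimentPlan.__dataclass_fields__) - {"toy"}
    kw = {k: v for k, v in mapping.items() if k in fields}
    return ExperimentPlan(toy=toy, **kw)
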