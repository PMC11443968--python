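"""TOML configuration loading.

A config file may carry three optional sections::

    [track]       # TrackGeometry fields
    tunnel_length = 50.0

    [sim]         # SimParams fields (all fixed model parameters)
    dt = 0.05
    tau = 1.6

    [conditions]  # either labels = ["0_0", "4_-8", ...] or omitted (default set)
    labels = ["0_0"]

Anything omitted falls back to the package defaults.
"""

from __future__ import annotations

import tomllib
from pathlib import Path

from .scenario import Condition, SimParams, TrackGeometry, default_condition_set

__all__ = ["load_config"]


def load_config(path) -> tuple[TrackGeometry, SimParams, list[Condition]]:
    """Read (geometry, params, conditions) from a TOML file."""
    with open(Path(path), "rb") as fh:
        raw = tomllib.load(fh)
    unknown = set(raw) - {"track", "sim", "conditions"}
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    geometry = TrackGeometry(**raw.get("track", {}))
    params = SimParams(**raw.get("sim", {}))
    cond_section = raw.get("conditions", {})
    if "labels" in cond_section:
        conditions = [Condition.from_label(lbl) for lbl in cond_section["labels"]]
    else:
        conditions = default_condition_set()
    return geometry, params, conditions
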