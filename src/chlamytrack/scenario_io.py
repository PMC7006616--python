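"""TOML serialization of simulation scenarios.

The on-disk form mirrors the :class:`~chlamytrack.simulate.SimScenario`
fields, with subpopulations as an array of tables and the optional light
bias as a sub-table. Reading uses the standard-library ``tomllib``; writing
uses a small emitter sufficient for this flat structure.
"""

from __future__ import annotations

import os
import tomllib
from dataclasses import asdict

from .errors import ValidationError
from .simulate import LightBias, SimScenario, SubPop

__all__ = ["scenario_to_toml", "scenario_from_toml", "write_scenario", "read_scenario"]


def _fmt(value) -> str:
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, str):
        return '"' + value.replace("\\", "\\\\").replace('"', '\\"') + '"'
    return repr(value)


def scenario_to_toml(scenario: SimScenario) -> str:
    d = asdict(scenario)
    subpops = d.pop("subpopulations")
    light = d.pop("light_bias")
    lines = [f"{k} = {_fmt(v)}" for k, v in d.items()]
    if light is not None:
        lines.append("")
        lines.append("[light_bias]")
        lines += [f"{k} = {_fmt(v)}" for k, v in light.items()]
    for sp in subpops:
        lines.append("")
        lines.append("[[subpopulations]]")
        lines += [f"{k} = {_fmt(v)}" for k, v in sp.items()]
    return "\n".join(lines) + "\n"


def scenario_from_toml(text: str) -> SimScenario:
    data = tomllib.loads(text)
    try:
        subpops = tuple(SubPop(**sp) for sp in data.pop("subpopulations", []))
        light = data.pop("light_bias", None)
        if light is not None:
            light = LightBias(**light)
        if subpops:
            return SimScenario(subpopulations=subpops, light_bias=light, **data)
        return SimScenario(light_bias=light, **data)
    except TypeError as exc:
        raise ValidationError(f"invalid scenario TOML: {exc}") from exc


def write_scenario(scenario: SimScenario, path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(scenario_to_toml(scenario))


def read_scenario(path: str | os.PathLike) -> SimScenario:
    with open(path, "rb") as fh:
        return scenario_from_toml(fh.read().decode("utf-8"))
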