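"""Run configuration: schema, validation, serialization and templates.

A run is described by a small structured-text document (YAML; JSON is a
subset) with the following top-level keys::

    circuit:        template name (required)
    parameters:     mapping of parameter overrides
    initial_state:  mapping state name -> value (missing states start at 0)
    horizon:        simulation horizon (model time units)
    n_points:       output grid density
    events:         list of {time, parameter, action: set|scale, value}
    scan:           optional {axis1, axis2, grid1: [lo, hi, n], grid2, contour}
    analysis:       list of report names to produce
    seed:           integer used when the config was fixture-generated
    notes:          free-form metadata (ignored by the engine)

Validation is strict: unknown top-level keys, unknown parameters and
unknown states are rejected, and every violation found is reported at once.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Callable

import yaml

from .errors import ConfigurationError
from .intracellular import (
    layered_gene_expression_circuit,
    minimal_gene_expression_circuit,
    operon_ratio_circuit,
    ratiometric_gene_expression_circuit,
)
from .model import CircuitModel
from .population import (
    coculture_ratio_circuit,
    consortium_circuit,
    population_control_circuit,
)
from .simulate import DisturbanceEvent

__all__ = ["RunConfig", "TEMPLATES", "build_circuit", "load_config", "save_config"]

TEMPLATES: dict[str, Callable[..., CircuitModel]] = {
    "minimal_gene_expression": minimal_gene_expression_circuit,
    "layered_gene_expression": layered_gene_expression_circuit,
    # the embedded control task is the layered loop plus a Q0 load term
    "embedded_gene_expression": layered_gene_expression_circuit,
    "ratiometric_gene_expression": ratiometric_gene_expression_circuit,
    "operon_ratio": operon_ratio_circuit,
    "consortium": consortium_circuit,
    "population_control": population_control_circuit,
    "coculture_ratio": coculture_ratio_circuit,
}

_TOP_LEVEL_KEYS = {
    "circuit", "parameters", "initial_state", "horizon", "n_points",
    "events", "scan", "analysis", "seed", "notes",
}
_EVENT_KEYS = {"time", "parameter", "action", "value"}
_SCAN_KEYS = {"axis1", "axis2", "grid1", "grid2", "contour"}


@dataclass
class RunConfig:
    """A validated, runnable simulation configuration."""

    circuit: str
    parameters: dict[str, float] = field(default_factory=dict)
    initial_state: dict[str, float] = field(default_factory=dict)
    horizon: float = 100.0
    n_points: int = 400
    events: list[dict] = field(default_factory=list)
    scan: dict | None = None
    analysis: list[str] = field(default_factory=list)
    seed: int | None = None
    notes: dict = field(default_factory=dict)

    def build(self) -> CircuitModel:
        return build_circuit(self.circuit, self.parameters)

    def event_objects(self) -> list[DisturbanceEvent]:
        return [DisturbanceEvent(e["time"], e["parameter"],
                                 e.get("action", "set"), e["value"])
                for e in self.events]

    def to_dict(self) -> dict:
        d = asdict(self)
        if d["scan"] is None:
            d.pop("scan")
        if d["seed"] is None:
            d.pop("seed")
        return d


def build_circuit(name: str, parameters: dict[str, float] | None = None) -> CircuitModel:
    """Instantiate a circuit template with parameter overrides."""
    if name not in TEMPLATES:
        raise ConfigurationError(
            f"unknown circuit template {name!r}; available: {sorted(TEMPLATES)}"
        )
    return TEMPLATES[name](**(parameters or {}))


def _validate(raw: dict) -> list[str]:
    problems: list[str] = []
    if not isinstance(raw, dict):
        return [f"config root must be a mapping, got {type(raw).__name__}"]
    unknown = set(raw) - _TOP_LEVEL_KEYS
    for key in sorted(unknown):
        problems.append(f"unknown top-level key {key!r}")
    circuit = raw.get("circuit")
    if not circuit:
        problems.append("missing required key 'circuit'")
        return problems
    if circuit not in TEMPLATES:
        problems.append(
            f"unknown circuit template {circuit!r}; available: {sorted(TEMPLATES)}"
        )
        return problems
    reference = TEMPLATES[circuit]()
    known_params = set(reference.params)
    known_states = set(reference.state_names)

    params = raw.get("parameters") or {}
    if not isinstance(params, dict):
        problems.append("'parameters' must be a mapping")
        params = {}
    for key, value in params.items():
        if key not in known_params:
            problems.append(f"unknown parameter path 'parameters.{key}'")
        elif not isinstance(value, (int, float)):
            problems.append(f"'parameters.{key}' must be numeric, got {type(value).__name__}")

    init = raw.get("initial_state") or {}
    if not isinstance(init, dict):
        problems.append("'initial_state' must be a mapping")
        init = {}
    for key, value in init.items():
        if key not in known_states:
            problems.append(f"unknown state 'initial_state.{key}' "
                            f"(states: {sorted(known_states)})")
        elif not isinstance(value, (int, float)):
            problems.append(f"'initial_state.{key}' must be numeric")
        elif value < 0:
            problems.append(f"'initial_state.{key}' must be >= 0")

    horizon = raw.get("horizon", 100.0)
    if not isinstance(horizon, (int, float)) or horizon < 0:
        problems.append("'horizon' must be a non-negative number")

    for i, ev in enumerate(raw.get("events") or []):
        if not isinstance(ev, dict):
            problems.append(f"'events[{i}]' must be a mapping")
            continue
        missing = {"time", "parameter", "value"} - set(ev)
        for key in sorted(missing):
            problems.append(f"'events[{i}]' missing key {key!r}")
        for key in sorted(set(ev) - _EVENT_KEYS):
            problems.append(f"'events[{i}]' has unknown key {key!r}")
        if "parameter" in ev and ev["parameter"] not in known_params:
            problems.append(f"'events[{i}].parameter' {ev['parameter']!r} "
                            "is not a parameter of this circuit")
        if ev.get("action", "set") not in ("set", "scale"):
            problems.append(f"'events[{i}].action' must be 'set' or 'scale'")
        if "time" in ev and isinstance(horizon, (int, float)) and \
                isinstance(ev["time"], (int, float)) and not 0 <= ev["time"] <= horizon:
            problems.append(f"'events[{i}].time' outside [0, horizon]")

    scan = raw.get("scan")
    if scan is not None:
        if not isinstance(scan, dict):
            problems.append("'scan' must be a mapping")
        else:
            for key in sorted(set(scan) - _SCAN_KEYS):
                problems.append(f"'scan' has unknown key {key!r}")
            for axis in ("axis1", "axis2"):
                if axis not in scan:
                    problems.append(f"'scan' missing key {axis!r}")
                elif scan[axis] not in known_params:
                    problems.append(f"'scan.{axis}' {scan[axis]!r} is not a parameter")
            for grid in ("grid1", "grid2"):
                g = scan.get(grid)
                if g is not None and (not isinstance(g, (list, tuple)) or len(g) != 3):
                    problems.append(f"'scan.{grid}' must be [lo, hi, n]")
            if "contour" in scan and scan["contour"] not in known_states:
                problems.append(f"'scan.contour' {scan['contour']!r} is not a state")
    return problems


def load_config(path: str | Path | dict) -> RunConfig:
    """Load and validate a run configuration from YAML/JSON (or a dict).

    Raises :class:`ConfigurationError` listing *all* violations found, each
    naming the offending key.
    """
    if isinstance(path, dict):
        raw = path
        origin = "<dict>"
    else:
        origin = str(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    problems = _validate(raw)
    if problems:
        raise ConfigurationError(
            f"invalid configuration ({origin}): " + "; ".join(problems)
        )
    return RunConfig(
        circuit=raw["circuit"],
        parameters={k: float(v) for k, v in (raw.get("parameters") or {}).items()},
        initial_state={k: float(v) for k, v in (raw.get("initial_state") or {}).items()},
        horizon=float(raw.get("horizon", 100.0)),
        n_points=int(raw.get("n_points", 400)),
        events=[dict(e) for e in (raw.get("events") or [])],
        scan=dict(raw["scan"]) if raw.get("scan") else None,
        analysis=list(raw.get("analysis") or []),
        seed=raw.get("seed"),
        notes=dict(raw.get("notes") or {}),
    )


def save_config(config: RunConfig, path: str | Path) -> None:
    """Serialize a config; ``load_config(save_config(c)) == c`` (round trip)."""
    path = Path(path)
    payload = config.to_dict()
    with open(path, "w") as fh:
        if path.suffix == ".json":
            json.dump(payload, fh, indent=2, sort_keys=True)
        else:
            yaml.safe_dump(payload, fh, sort_keys=False)
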