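"""Assembled ODE circuit models.

A :class:`CircuitModel` bundles a right-hand side with named states, a flat
parameter dictionary (keys double as the parameter paths used by disturbance
events and stability scans), derived read-outs such as the free-resource
level, and optional closed-form helpers (set-points, equilibria).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .errors import ConfigurationError

__all__ = ["CircuitModel"]


@dataclass
class CircuitModel:
    """An ODE system ``dy/dt = rhs(t, y, params)`` with named states.

    Attributes
    ----------
    name:
        Template name of the circuit.
    state_names:
        Ordered labels of the state vector.
    params:
        Flat mapping of parameter name -> value.  Mutated copies are used by
        the event machinery; the stored dict is treated as the nominal set.
    rhs:
        ``rhs(t, y, params) -> dy`` (vectorized over the state only).
    derived:
        Mapping of column name -> ``f(y, params)`` for derived read-outs
        (free resource, total population, ...).
    output:
        Name of the regulated output state, when the circuit has one.
    """

    name: str
    state_names: list[str]
    params: dict[str, float]
    rhs: Callable[[float, np.ndarray, Mapping[str, float]], np.ndarray]
    derived: dict[str, Callable[[np.ndarray, Mapping[str, float]], float]] = field(
        default_factory=dict
    )
    output: str | None = None
    meta: dict = field(default_factory=dict)

    def index(self, state: str) -> int:
        try:
            return self.state_names.index(state)
        except ValueError:
            raise ConfigurationError(
                f"unknown state {state!r}; known: {self.state_names}"
            ) from None

    def state_vector(self, mapping: Mapping[str, float]) -> np.ndarray:
        """Build a state vector from a name -> value mapping (missing = 0)."""
        unknown = set(mapping) - set(self.state_names)
        if unknown:
            raise ConfigurationError(f"unknown state names: {sorted(unknown)}")
        return np.array([float(mapping.get(s, 0.0)) for s in self.state_names])

    def with_params(self, **updates: float) -> "CircuitModel":
        """Copy of the model with selected parameters replaced."""
        unknown = set(updates) - set(self.params)
        if unknown:
            raise ConfigurationError(f"unknown parameters: {sorted(unknown)}")
        params = dict(self.params)
        params.update(updates)
        return CircuitModel(
            self.name, list(self.state_names), params, self.rhs,
            dict(self.derived), self.output, dict(self.meta),
        )

    def check_parameter(self, path: str) -> None:
        if path not in self.params:
            raise ConfigurationError(
                f"unknown parameter path {path!r} for circuit {self.name!r}"
            )

    def hash(self) -> str:
        payload = json.dumps(
            {"name": self.name, "states": self.state_names,
             "params": {k: float(v) for k, v in sorted(self.params.items())}},
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]
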