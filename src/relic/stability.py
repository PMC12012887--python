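"""Equilibrium finding, linear stability and parametric stability scans."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import root

from .errors import DomainError, InputError
from .model import CircuitModel
from .simulate import steady_state

__all__ = [
    "EquilibriumReport",
    "StabilityMap",
    "find_positive_equilibrium",
    "local_stability",
    "numerical_jacobian",
    "stability_region_scan",
    "adaptation_error",
]

#: Eigenvalues with |Re| below this margin count as marginal, not stable.
DEFAULT_MARGIN = 1e-8
#: Coordinates must exceed this threshold for an equilibrium to count as
#: strictly positive (model units).
POSITIVITY_THRESHOLD = 1e-9
RESIDUAL_TOL = 1e-10


@dataclass
class EquilibriumReport:
    """A located equilibrium with its local spectrum."""

    state: np.ndarray
    residual: float
    positivity: bool
    eigenvalues: np.ndarray
    stable: bool
    marginal: bool = False
    found: bool = True
    message: str = ""

    def value(self, model: CircuitModel, name: str) -> float:
        return float(self.state[model.index(name)])


@dataclass
class StabilityMap:
    """Verdicts of a two-parameter stability scan."""

    axis1: str
    axis2: str
    grid1: np.ndarray
    grid2: np.ndarray
    verdicts: np.ndarray  # bool, shape (len(grid1), len(grid2))
    contours: np.ndarray | None = None
    failures: list[tuple[int, int, str]] = field(default_factory=list)

    def __post_init__(self):
        expected = (len(self.grid1), len(self.grid2))
        if self.verdicts.shape != expected:
            raise InputError(f"verdict grid shape {self.verdicts.shape} != {expected}")
        if self.contours is not None and self.contours.shape != expected:
            raise InputError("contour grid shape mismatch")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, v1 in enumerate(self.grid1):
            for j, v2 in enumerate(self.grid2):
                row = {self.axis1: v1, self.axis2: v2,
                       "stable": bool(self.verdicts[i, j])}
                if self.contours is not None:
                    row["setpoint"] = self.contours[i, j]
                rows.append(row)
        return pd.DataFrame(rows)


def numerical_jacobian(
    f: Callable[[np.ndarray], np.ndarray], x: np.ndarray
) -> np.ndarray:
    """Central-difference Jacobian with step ``max(1e-6, 1e-6 |x_i|)``."""
    x = np.asarray(x, float)
    n = x.size
    J = np.empty((n, n))
    for i in range(n):
        h = max(1e-6, 1e-6 * abs(x[i]))
        xp, xm = x.copy(), x.copy()
        xp[i] += h
        xm[i] -= h
        J[:, i] = (np.asarray(f(xp)) - np.asarray(f(xm))) / (2 * h)
    return J


def local_stability(
    model: CircuitModel,
    equilibrium: np.ndarray,
    margin: float = DEFAULT_MARGIN,
    params: Mapping[str, float] | None = None,
) -> tuple[bool, np.ndarray]:
    """Linearize at an equilibrium and test ``max Re(lambda) < -margin``.

    Returns ``(stable, eigenvalues)``.  Spectra with ``|Re| <= margin``
    eigenvalues are marginal and reported as not stable.  An ill-conditioned
    Jacobian triggers a warning with the condition estimate.
    """
    p = dict(params if params is not None else model.params)
    J = numerical_jacobian(lambda y: model.rhs(0.0, y, p), np.asarray(equilibrium, float))
    cond = np.linalg.cond(J)
    if not np.isfinite(cond) or cond > 1e12:
        warnings.warn(f"Jacobian ill-conditioned (cond ~ {cond:.2e}); "
                      "eigenvalues may be unreliable", RuntimeWarning, stacklevel=2)
    eig = np.linalg.eigvals(J)
    return bool(np.max(eig.real) < -margin), eig


def find_positive_equilibrium(
    model: CircuitModel,
    seed_state: np.ndarray | Mapping[str, float],
    params: Mapping[str, float] | None = None,
    margin: float = DEFAULT_MARGIN,
    positivity_threshold: float = POSITIVITY_THRESHOLD,
    pre_integrate: float = 500.0,
) -> EquilibriumReport:
    """Locate the equilibrium reached from ``seed_state`` and classify it.

    Forward integration from the seed pulls the search into the right basin
    (this is also the tie-break when several roots exist), followed by a
    Newton polish; the report carries the residual, strict-positivity flag
    (threshold 1e-9 in model units) and the local spectrum.
    """
    p = dict(params if params is not None else model.params)
    y0 = (np.asarray(seed_state, float)
          if not isinstance(seed_state, Mapping)
          else model.state_vector(seed_state))
    ss = steady_state(model, y0, params=p, first_horizon=pre_integrate)
    y = ss.state
    sol = root(lambda yy: model.rhs(0.0, yy, p), y, method="hybr",
               options={"xtol": 1e-13})
    if sol.success:
        y = sol.x
    residual = float(np.max(np.abs(model.rhs(0.0, y, p))))
    if residual > RESIDUAL_TOL and not ss.converged:
        return EquilibriumReport(
            state=y, residual=residual, positivity=False,
            eigenvalues=np.array([]), stable=False, found=False,
            message=ss.message or "no equilibrium found from seed",
        )
    positivity = bool(np.all(y > positivity_threshold))
    stable, eig = local_stability(model, y, margin=margin, params=p)
    marginal = bool(np.any(np.abs(eig.real) <= margin))
    return EquilibriumReport(
        state=y, residual=residual, positivity=positivity,
        eigenvalues=eig, stable=stable and not marginal, marginal=marginal,
    )


def stability_region_scan(
    model: CircuitModel,
    axis1: str,
    axis2: str,
    grid1: Sequence[float],
    grid2: Sequence[float],
    seed_state: np.ndarray | Mapping[str, float],
    contour: str | None = None,
    margin: float = DEFAULT_MARGIN,
) -> StabilityMap:
    """Positive-equilibrium + stability verdict over a 2-D parameter grid.

    Each cell is evaluated independently (statelessly) at the nominal
    parameters with the two axis values substituted; verdicts are
    ``found and strictly positive and stable``.  Per-cell failures are
    recorded in ``failures`` and never abort the scan.  ``contour`` names a
    state whose equilibrium value is collected (the regulated steady state
    contour lines of a set-point map).
    """
    model.check_parameter(axis1)
    model.check_parameter(axis2)
    g1 = np.asarray(grid1, float)
    g2 = np.asarray(grid2, float)
    verdicts = np.zeros((g1.size, g2.size), dtype=bool)
    contours = np.full((g1.size, g2.size), np.nan) if contour else None
    failures: list[tuple[int, int, str]] = []
    for i, v1 in enumerate(g1):
        for j, v2 in enumerate(g2):
            p = dict(model.params)
            p[axis1] = float(v1)
            p[axis2] = float(v2)
            try:
                rep = find_positive_equilibrium(model, seed_state, params=p,
                                                margin=margin)
                verdicts[i, j] = rep.found and rep.positivity and rep.stable
                if contour and rep.found and rep.positivity:
                    contours[i, j] = rep.value(model, contour)
            except Exception as exc:  # noqa: BLE001 - per-cell isolation
                failures.append((i, j, f"{type(exc).__name__}: {exc}"))
    return StabilityMap(axis1, axis2, g1, g2, verdicts, contours, failures)


def adaptation_error(pre_steady: float, post_steady: float) -> float:
    """Normalized post-disturbance steady-state deviation ``e_p``.

    With ``d1`` the pre-disturbance steady state and ``d2`` the post-minus-
    pre deviation, ``e_p = (d1 + d2)/d1 = post/pre``; ``e_p = 1`` is perfect
    adaptation.
    """
    if not pre_steady > 0:
        raise DomainError(f"pre-disturbance steady state must be > 0, got {pre_steady}")
    return float(post_steady) / float(pre_steady)
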