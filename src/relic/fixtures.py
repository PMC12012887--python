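"""Seeded random parameterizations (fixtures) with constraint filters.

Fixture generation draws circuit parameters from documented ranges and
rejection-samples until the requested constraints hold, so that tests and
scans can exercise many qualitatively equivalent operating points.  The
same seed always yields the same configuration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import RunConfig, TEMPLATES, build_circuit
from .errors import ConfigurationError, FixtureError
from .intracellular import (
    GeneExpressionPlantParams,
    feasibility_conditions,
    layered_equilibrium,
    stability_criterion,
)
from .motifs import LayeredMotifParams, RatiometricParams, ratio_setpoint_linear
from .resources import ResourcePool
from .stability import find_positive_equilibrium

__all__ = ["generate_fixture", "PARAMETER_RANGES"]

#: Log-uniform sampling ranges per template (subset of parameters varied).
PARAMETER_RANGES: dict[str, dict[str, tuple[float, float]]] = {
    "layered_gene_expression": {
        "alpha1_star": (0.2, 2.0),
        "alpha2_star": (0.05, 1.0),
        "gamma_c2": (0.05, 0.5),
        "sense_gain": (0.2, 2.0),
        "k_star": (0.5, 5.0),
        "b_p1_star": (0.01, 0.3),
        "gamma_p1": (0.5, 2.0),
        "w1": (0.2, 2.0),
        "w2": (0.2, 2.0),
        "R_tot": (30.0, 300.0),
        "Q0": (1e-4, 1e-2),
    },
    "ratiometric_gene_expression": {
        "alpha1_star": (0.3, 2.0),
        "alpha2_star": (0.2, 1.0),
        "gamma_c2": (0.3, 2.0),
        "sense_gain": (0.2, 1.0),
        "k_star": (0.5, 3.0),
        "b_p2_star": (0.3, 2.0),
        "gamma_x1": (0.5, 2.0),
        "gamma_x2": (0.5, 2.0),
        "R_tot": (30.0, 300.0),
    },
    "coculture_ratio": {
        "rho3": (0.3, 1.0),
        "rho4": (0.5, 4.0),
        "gamma": (0.05, 0.2),
    },
    "minimal_gene_expression": {
        "alpha1_star": (0.5, 2.0),
        "sense_gain": (0.5, 2.0),
        "k_star": (0.5, 3.0),
        "w_z1": (1.0, 8.0),
        "w_bar_lin": (0.2, 2.0),
        "R_tot": (30.0, 300.0),
    },
}


def _constraint_feasible(params: dict) -> bool:
    plant = GeneExpressionPlantParams(
        b_p1_star=params["b_p1_star"], gamma_p1=params["gamma_p1"],
        k_star=params["k_star"],
    )
    ctrl = LayeredMotifParams(
        alpha1_star=params["alpha1_star"], alpha2_star=params["alpha2_star"],
        gamma_c2=params["gamma_c2"], sense_gain=params["sense_gain"],
        k_star=params["k_star"], w1=params["w1"], w2=params["w2"],
    )
    pool = ResourcePool("pool", params["R_tot"], params["Q0"])
    c1, c2 = feasibility_conditions(plant, ctrl, pool)
    # the closed form gives the exact z1*, z2* positivity on top of the
    # conservative printed conditions
    return c1 and c2 and layered_equilibrium(params)["feasible"]


def _constraint_stability_criterion(params: dict) -> bool:
    plant = GeneExpressionPlantParams(
        b_p1_star=params["b_p1_star"], gamma_p1=params["gamma_p1"],
        k_star=params["k_star"],
    )
    ctrl = LayeredMotifParams(
        alpha1_star=params["alpha1_star"], alpha2_star=params["alpha2_star"],
        gamma_c2=params["gamma_c2"], sense_gain=params["sense_gain"],
        k_star=params["k_star"], w1=params["w1"], w2=params["w2"],
    )
    return stability_criterion(plant, ctrl)


def _constraint_stable_numeric(params: dict, template: str) -> bool:
    model = build_circuit(template, params)
    if template == "layered_gene_expression":
        eq = layered_equilibrium(params)
        seed = {"x1": eq["x1"], "z1": max(eq["z1"], 1e-3), "z2": max(eq["z2"], 1e-3)}
    elif template == "ratiometric_gene_expression":
        seed = {"x1": 1.0, "x2": 1.0, "z1": 0.5, "z2": 1.0}
    else:
        seed = {name: 1.0 for name in model.state_names}
    rep = find_positive_equilibrium(model, seed)
    return rep.found and rep.positivity and rep.stable


CONSTRAINTS = {
    "feasible": lambda params, template: _constraint_feasible(params),
    "stability_criterion": lambda params, template: _constraint_stability_criterion(params),
    "stable_layered": lambda params, template: (
        _constraint_feasible(params)
        and _constraint_stability_criterion(params)
    ),
    "stable_numeric": _constraint_stable_numeric,
}


def generate_fixture(
    template: str,
    seed: int,
    constraints: tuple[str, ...] | list[str] = (),
    budget: int = 2000,
) -> tuple[RunConfig, int]:
    """Sample a reproducible parameterization satisfying the constraints.

    Returns ``(config, n_rejections)``.  Raises :class:`FixtureError` when
    the constraint set cannot be satisfied within ``budget`` draws.
    """
    if template not in TEMPLATES:
        raise ConfigurationError(f"unknown template {template!r}")
    ranges = PARAMETER_RANGES.get(template)
    if ranges is None:
        raise ConfigurationError(
            f"no documented sampling ranges for template {template!r}; "
            f"available: {sorted(PARAMETER_RANGES)}"
        )
    for c in constraints:
        if c not in CONSTRAINTS:
            raise ConfigurationError(
                f"unknown constraint {c!r}; available: {sorted(CONSTRAINTS)}"
            )
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(budget):
        params = {
            name: float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            for name, (lo, hi) in ranges.items()
        }
        if all(CONSTRAINTS[c](params, template) for c in constraints):
            reference = build_circuit(template)
            full = dict(reference.params)
            full.update(params)
            return (
                RunConfig(
                    circuit=template,
                    parameters=full,
                    seed=seed,
                    notes={"n_rejections": rejections,
                           "constraints": list(constraints)},
                ),
                rejections,
            )
        rejections += 1
    raise FixtureError(
        f"could not satisfy constraints {list(constraints)} for {template!r} "
        f"within {budget} draws", n_rejections=rejections,
    )
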