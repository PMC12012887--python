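"""Reduced-model vs. full mass-action cross-validation.

Random small competitive networks are expanded to their elementary
mass-action form and integrated; the free-resource and product trajectories
are compared against the reduced quasi-steady-state rate laws.  The
comparison discards an initial boundary layer of duration ``10 * epsilon``
during which the fast binding intermediates equilibrate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .resources import (
    CompetitiveReaction,
    ReactionKind,
    ResourcePool,
    expand_to_mass_action,
    free_resource_concentration,
    production_rate,
)

__all__ = ["OracleComparison", "compare_network", "random_network", "run_oracle_suite"]

_ORACLE_KINDS = (
    ReactionKind.ZEROTH,
    ReactionKind.UNIMOLECULAR,
    ReactionKind.BIMOLECULAR_S1,
    ReactionKind.BIMOLECULAR_S2,
)


@dataclass
class OracleComparison:
    """Outcome of one reduced-vs-full comparison at a fixed epsilon."""

    epsilon: float
    sup_error: float  # worst relative sup-norm error over products and free R
    conservation_error: float  # worst relative drift of total resource
    n_reactions: int


def random_network(rng: np.random.Generator, max_reactions: int = 3):
    """Sample a small competitive network with moderate occupancies.

    Rates are drawn so that the complexed fraction of each substrate stays
    small (resource scarce relative to substrates), the regime in which the
    reduced description applies.
    """
    n = int(rng.integers(1, max_reactions + 1))
    pool = ResourcePool("pool", R_tot=float(rng.uniform(0.05, 0.3)))
    reactions = []
    rates = {}
    concs = {}
    for i in range(n):
        kind = _ORACLE_KINDS[rng.integers(0, len(_ORACLE_KINDS))]
        kcat = float(rng.uniform(0.5, 2.0))
        if kind is ReactionKind.ZEROTH:
            reactions.append(CompetitiveReaction(kind, 0.0, (), f"P{i}", "pool"))
            rates[i] = {"a": float(rng.uniform(0.05, 0.3)),
                        "d": float(rng.uniform(0.5, 2.0)), "kcat": kcat}
        elif kind is ReactionKind.UNIMOLECULAR:
            s = f"S{i}"
            concs[s] = float(rng.uniform(0.5, 2.0))
            reactions.append(CompetitiveReaction(kind, 0.0, (s,), f"P{i}", "pool"))
            rates[i] = {"a": float(rng.uniform(0.05, 0.3)),
                        "d": float(rng.uniform(0.5, 2.0)), "kcat": kcat}
        else:
            a_sp, b_sp = f"A{i}", f"B{i}"
            concs[a_sp] = float(rng.uniform(0.5, 1.5))
            concs[b_sp] = float(rng.uniform(0.5, 1.5))
            reactions.append(
                CompetitiveReaction(kind, 0.0, (a_sp, b_sp), f"P{i}", "pool")
            )
            rates[i] = {"a1": float(rng.uniform(0.05, 0.3)),
                        "d1": float(rng.uniform(0.5, 2.0)),
                        "a2": float(rng.uniform(0.05, 0.3)),
                        "d2": float(rng.uniform(0.5, 2.0)), "kcat": kcat}
    return pool, reactions, rates, concs


def compare_network(
    pool: ResourcePool,
    reactions,
    rates,
    concs,
    epsilon: float,
    horizon: float = 30.0,
    n_points: int = 60,
) -> OracleComparison:
    """Integrate the elementary network and compare against the reduced laws.

    The horizon is fixed across epsilon values (and must exceed the fast
    layer ``10 * epsilon``) so that sup-norm errors at different epsilon are
    directly comparable.
    """
    if horizon <= 10.0 * epsilon:
        raise ValueError("horizon must exceed the fast layer 10*epsilon")
    exp = expand_to_mass_action(pool, reactions, rates, epsilon)
    y0 = exp.initial_state(concs)
    t_eval = np.linspace(0.0, horizon, n_points)
    sol = solve_ivp(exp.rhs, (0.0, horizon), y0, method="LSODA",
                    rtol=1e-10, atol=1e-12, t_eval=t_eval)
    if not sol.success:  # pragma: no cover - networks are well conditioned
        raise RuntimeError(f"full-network integration failed: {sol.message}")

    # conservation of total resource along the trajectory
    totals = np.array([exp.resource_total(sol.y[:, k]) for k in range(sol.t.size)])
    cons_err = float(np.max(np.abs(totals - pool.R_tot)) / pool.R_tot)

    # reduced prediction from the induced (lumped) reaction set
    r_pred = free_resource_concentration(exp.pool, exp.induced, concs)
    mask = sol.t >= 10.0 * epsilon
    sup = 0.0
    r_traj = np.array([exp.free_resource(sol.y[:, k]) for k in range(sol.t.size)])
    sup = max(sup, float(np.max(np.abs(r_traj[mask] - r_pred) / r_pred)))
    rates_by_product: dict[str, float] = {}
    for rxn in exp.induced:
        v = production_rate(rxn, concs, r_pred)
        rates_by_product[rxn.product] = rates_by_product.get(rxn.product, 0.0) + v
    for product, v in rates_by_product.items():
        p_pred = v * sol.t
        p_traj = np.array(
            [exp.concentration(sol.y[:, k], product) for k in range(sol.t.size)]
        )
        scale = max(float(np.max(np.abs(p_pred[mask]))), 1e-12)
        sup = max(sup, float(np.max(np.abs(p_traj[mask] - p_pred[mask]))) / scale)
    return OracleComparison(epsilon, sup, cons_err, len(reactions))


def run_oracle_suite(
    seed: int,
    n_networks: int = 20,
    epsilons=(1.0, 1e-1, 1e-3),
    horizon: float = 30.0,
):
    """Compare reduced and full models over a batch of random networks.

    Returns a list of per-network lists of :class:`OracleComparison`
    (one entry per epsilon, in the given order).
    """
    rng = np.random.default_rng(seed)
    results = []
    for _ in range(n_networks):
        pool, reactions, rates, concs = random_network(rng)
        results.append([
            compare_network(pool, reactions, rates, concs, eps, horizon)
            for eps in epsilons
        ])
    return results
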