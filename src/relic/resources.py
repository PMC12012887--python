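"""Resource-aware rate laws for shared catalytic resource pools.

Production reactions in a cell often draw on a common pool of catalytic
resources (ribosomes, RNA polymerases, proteases, nutrients, ...).  When the
pool is finite, every reaction that occupies it depresses the free-resource
concentration seen by all the others, coupling otherwise independent parts of
a circuit.  This module implements the reduced quasi-steady-state description
of that coupling and, as a validation oracle, the full elementary mass-action
networks the reduction is derived from.

Reduced description
-------------------
With ``q0`` zeroth-order, ``q1`` unimolecular and ``q2`` bimolecular
resource-limited catalytic reactions competing for one pool, the free
resource concentration is

    r = R_eff / (1 + sum_i w_i^u s_i + sum_i (w_i^ab a_i b_i + w_i^a a_i))

where ``R_eff = R_tot / (1 + Q0)`` is the effective pool capacity after the
aggregate zeroth-order load ``Q0``, and the ``w`` are lumped *competition
gains*.  Production rates are then ``beta* r`` (zeroth order),
``beta* s r`` (unimolecular) and ``beta* a b r`` (bimolecular).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Mapping, Sequence

import numpy as np

from .errors import ConfigurationError, InputError

__all__ = [
    "ReactionKind",
    "ResourcePool",
    "CompetitiveReaction",
    "ElementaryReaction",
    "MassActionExpansion",
    "free_resource_concentration",
    "production_rate",
    "expand_to_mass_action",
]


class ReactionKind(str, Enum):
    """Closed enumeration of supported resource-limited catalytic reactions.

    The four bimolecular scenarios differ in the order in which substrates
    and resource assemble into the productive complex:

    * ``BIMOLECULAR_S1``: A + B <-> S_b, then S_b + R <-> C -> P (resource
      binds last; only the pairwise gain ``w_ab`` arises).
    * ``BIMOLECULAR_S2``: A + R <-> S_b, then S_b + B <-> C -> P (resource
      binds first; both ``w_ab`` and the single-substrate gain ``w_a``
      arise because S_b already sequesters resource).
    * ``BIMOLECULAR_S3`` / ``BIMOLECULAR_S4``: mirror images of 1 and 2 with
      the roles of A and B exchanged.
    """

    ZEROTH = "zeroth"
    UNIMOLECULAR = "unimolecular"
    BIMOLECULAR_S1 = "bimolecular_s1"
    BIMOLECULAR_S2 = "bimolecular_s2"
    BIMOLECULAR_S3 = "bimolecular_s3"
    BIMOLECULAR_S4 = "bimolecular_s4"


_NO_WA_KINDS = {ReactionKind.BIMOLECULAR_S1, ReactionKind.BIMOLECULAR_S3}
_BIMOLECULAR_KINDS = {
    ReactionKind.BIMOLECULAR_S1,
    ReactionKind.BIMOLECULAR_S2,
    ReactionKind.BIMOLECULAR_S3,
    ReactionKind.BIMOLECULAR_S4,
}


@dataclass(frozen=True)
class ResourcePool:
    """A conserved pool of shared catalytic resources.

    Parameters
    ----------
    pool_id:
        Name of the pool (e.g. ``"ribosomes"``).
    R_tot:
        Total resource concentration (a.u., > 0), conserved over the time
        interval of interest.
    Q0:
        Aggregate dimensionless load of all zeroth-order reactions drawing
        on the pool (>= 0).
    """

    pool_id: str
    R_tot: float
    Q0: float = 0.0

    def __post_init__(self):
        if not self.R_tot > 0:
            raise InputError(f"pool {self.pool_id!r}: R_tot must be > 0, got {self.R_tot}")
        if self.Q0 < 0:
            raise InputError(f"pool {self.pool_id!r}: Q0 must be >= 0, got {self.Q0}")

    @property
    def R_eff(self) -> float:
        """Effective capacity ``R_tot / (1 + Q0)``."""
        return self.R_tot / (1.0 + self.Q0)


@dataclass(frozen=True)
class CompetitiveReaction:
    """One resource-limited catalytic production reaction (reduced form).

    ``beta_star`` is the lumped production rate constant of the reduced rate
    law; ``w_u``, ``w_ab`` and ``w_a`` are the competition gains contributed
    to the free-resource denominator.  Substrates are referenced by name and
    looked up in the concentration mapping at evaluation time.  ``w_a`` is
    structurally zero for bimolecular scenarios 1 and 3, where no
    single-substrate resource complex exists.
    """

    kind: ReactionKind
    beta_star: float
    substrates: tuple[str, ...] = ()
    product: str = "P"
    pool_id: str = "pool"
    w_u: float = 0.0
    w_ab: float = 0.0
    w_a: float = 0.0

    def __post_init__(self):
        kind = ReactionKind(self.kind)
        object.__setattr__(self, "kind", kind)
        object.__setattr__(self, "substrates", tuple(self.substrates))
        if self.beta_star < 0:
            raise InputError("beta_star must be >= 0")
        for name in ("w_u", "w_ab", "w_a"):
            if getattr(self, name) < 0:
                raise InputError(f"{name} must be >= 0")
        if kind in _NO_WA_KINDS and self.w_a != 0.0:
            raise ConfigurationError(
                f"w_a is structurally zero for {kind.value}; got {self.w_a}"
            )
        n_expected = {ReactionKind.ZEROTH: 0, ReactionKind.UNIMOLECULAR: 1}.get(kind, 2)
        if len(self.substrates) != n_expected:
            raise ConfigurationError(
                f"{kind.value} reaction requires {n_expected} substrate(s), "
                f"got {len(self.substrates)}"
            )

    def occupancy(self, concs: Mapping[str, float]) -> float:
        """Contribution of this reaction to the free-resource denominator."""
        if self.kind is ReactionKind.ZEROTH:
            return 0.0  # zeroth-order load is carried by the pool's Q0
        if self.kind is ReactionKind.UNIMOLECULAR:
            return self.w_u * _conc(concs, self.substrates[0])
        a = _conc(concs, self.substrates[0])
        b = _conc(concs, self.substrates[1])
        return self.w_ab * a * b + self.w_a * a


def _conc(concs: Mapping[str, float], name: str) -> float:
    try:
        value = concs[name]
    except KeyError:
        raise InputError(f"missing substrate concentration for {name!r}") from None
    if value < 0:
        raise InputError(f"negative concentration for {name!r}: {value}")
    return float(value)


def free_resource_concentration(
    pool: ResourcePool,
    reactions: Sequence[CompetitiveReaction],
    substrate_concs: Mapping[str, float],
) -> float:
    """Free resource concentration of a pool under competitive load.

    Evaluates ``r = R_eff / (1 + sum of occupancy terms)``.  An empty
    reaction list is legal and returns ``R_eff``.  Raises
    :class:`ConfigurationError` if any reaction names a different pool.
    """
    denom = 1.0
    for rxn in reactions:
        if rxn.pool_id != pool.pool_id:
            raise ConfigurationError(
                f"reaction draws from pool {rxn.pool_id!r}, not {pool.pool_id!r}"
            )
        denom += rxn.occupancy(substrate_concs)
    return pool.R_eff / denom


def production_rate(
    reaction: CompetitiveReaction,
    substrate_concs: Mapping[str, float],
    r: float,
) -> float:
    """Reduced-model production rate given the free resource level ``r``."""
    if r < 0:
        raise InputError(f"free resource concentration must be >= 0, got {r}")
    if reaction.kind is ReactionKind.ZEROTH:
        return reaction.beta_star * r
    if reaction.kind is ReactionKind.UNIMOLECULAR:
        return reaction.beta_star * _conc(substrate_concs, reaction.substrates[0]) * r
    a = _conc(substrate_concs, reaction.substrates[0])
    b = _conc(substrate_concs, reaction.substrates[1])
    return reaction.beta_star * a * b * r


# ---------------------------------------------------------------------------
# Full elementary mass-action expansion (validation oracle)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ElementaryReaction:
    """A single elementary step: reactants -> products at mass-action `rate`."""

    reactants: tuple[str, ...]
    products: tuple[str, ...]
    rate: float
    label: str = ""


@dataclass
class MassActionExpansion:
    """Explicit elementary network for a set of competitive reactions.

    Binding/unbinding steps are accelerated by ``1/epsilon`` so that the
    intermediates equilibrate fast relative to catalysis; in the limit
    ``epsilon -> 0`` the network's free-resource trajectory converges to the
    reduced formula implemented by :func:`free_resource_concentration`.

    ``buffered_substrates`` (default) holds free substrate concentrations
    constant, matching the reduced model's regime where the substrate
    fraction locked in complexes is negligible; set it to ``False`` to let
    binding deplete free substrates (total substrate is then conserved).
    """

    pool: ResourcePool
    species: list[str]
    reactions: list[ElementaryReaction]
    epsilon: float
    resource_species: str
    resource_complexes: list[str]
    substrate_species: list[str]
    induced: list[CompetitiveReaction]
    buffered_substrates: bool = True
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self._index = {name: i for i, name in enumerate(self.species)}

    def initial_state(self, substrate_concs: Mapping[str, float]) -> np.ndarray:
        """All resource free, no complexes, substrates at the given levels."""
        y0 = np.zeros(len(self.species))
        y0[self._index[self.resource_species]] = self.pool.R_tot
        for name, value in substrate_concs.items():
            if name in self._index:
                y0[self._index[name]] = float(value)
        return y0

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        dy = np.zeros_like(y)
        idx = self._index
        frozen = set(self.substrate_species) if self.buffered_substrates else ()
        for rxn in self.reactions:
            flux = rxn.rate
            for sp in rxn.reactants:
                flux *= y[idx[sp]]
            for sp in rxn.reactants:
                if sp not in frozen:
                    dy[idx[sp]] -= flux
            for sp in rxn.products:
                if sp not in frozen:
                    dy[idx[sp]] += flux
        return dy

    def resource_total(self, y: np.ndarray) -> float:
        """Free resource plus all resource-sequestering complexes."""
        total = y[self._index[self.resource_species]]
        for sp in self.resource_complexes:
            total += y[self._index[sp]]
        return float(total)

    def free_resource(self, y: np.ndarray) -> float:
        return float(y[self._index[self.resource_species]])

    def concentration(self, y: np.ndarray, name: str) -> float:
        return float(y[self._index[name]])


def expand_to_mass_action(
    pool: ResourcePool,
    reactions: Sequence[CompetitiveReaction],
    elementary_rates: Mapping[int, Mapping[str, float]],
    epsilon: float,
) -> MassActionExpansion:
    """Build the explicit elementary network behind a reduced description.

    Parameters
    ----------
    elementary_rates:
        For each reaction index, a mapping with binding (``a``), unbinding
        (``d``) and catalysis (``kcat``) rate constants; bimolecular
        scenarios take two binding/unbinding pairs (``a1, d1, a2, d2``).
    epsilon:
        Timescale separation; binding and unbinding rates are multiplied by
        ``1/epsilon``.

    Returns a :class:`MassActionExpansion` whose ``induced`` attribute holds
    the reduced-model reactions with competition gains recomputed from the
    elementary rates via the quasi-steady-state lumping
    ``w = a / (d + epsilon * kcat) / (1 + Q0)`` and
    ``beta* = kcat * a / (d + epsilon * kcat)``.
    """
    if epsilon <= 0:
        raise InputError(f"epsilon must be > 0, got {epsilon}")

    R = f"R[{pool.pool_id}]"
    species: list[str] = [R]
    elem: list[ElementaryReaction] = []
    r_complexes: list[str] = []
    substrates: list[str] = []
    occupancies: list[tuple[CompetitiveReaction, float, Callable]] = []

    q0_total = 0.0
    # First pass: zeroth-order loads set Q0 of the induced pool.
    for i, rxn in enumerate(reactions):
        if rxn.pool_id != pool.pool_id:
            raise ConfigurationError(
                f"reaction {i} draws from pool {rxn.pool_id!r}, not {pool.pool_id!r}"
            )
        if ReactionKind(rxn.kind) is ReactionKind.ZEROTH:
            rates = dict(elementary_rates[i])
            q0_total += rates["a"] / (rates["d"] + epsilon * rates["kcat"])
    induced_pool = ResourcePool(pool.pool_id, pool.R_tot, pool.Q0 + q0_total)
    scale = 1.0 + induced_pool.Q0

    induced: list[CompetitiveReaction] = []
    for i, rxn in enumerate(reactions):
        kind = ReactionKind(rxn.kind)
        rates = dict(elementary_rates[i])
        kcat = rates["kcat"]
        tag = f"{i}"
        product = rxn.product or f"P{i}"
        if product not in species:
            species.append(product)

        if kind is ReactionKind.ZEROTH:
            c = f"C{tag}^z"
            species.append(c)
            r_complexes.append(c)
            a, d = rates["a"], rates["d"]
            elem += [
                ElementaryReaction((R,), (c,), a / epsilon, f"bind{tag}"),
                ElementaryReaction((c,), (R,), d / epsilon, f"unbind{tag}"),
                ElementaryReaction((c,), (product, R), kcat, f"cat{tag}"),
            ]
            induced.append(
                CompetitiveReaction(
                    kind, kcat * a / (d + epsilon * kcat), (), product, pool.pool_id
                )
            )
        elif kind is ReactionKind.UNIMOLECULAR:
            s = rxn.substrates[0]
            c = f"C{tag}^u"
            for sp in (s, c):
                if sp not in species:
                    species.append(sp)
            if s not in substrates:
                substrates.append(s)
            r_complexes.append(c)
            a, d = rates["a"], rates["d"]
            elem += [
                ElementaryReaction((s, R), (c,), a / epsilon, f"bind{tag}"),
                ElementaryReaction((c,), (s, R), d / epsilon, f"unbind{tag}"),
                ElementaryReaction((c,), (product, s, R), kcat, f"cat{tag}"),
            ]
            ahat = a / (d + epsilon * kcat)
            induced.append(
                CompetitiveReaction(
                    kind, kcat * ahat, (s,), product, pool.pool_id, w_u=ahat / scale
                )
            )
        elif kind in _BIMOLECULAR_KINDS:
            # Mirror scenarios exchange the substrate roles.
            if kind in (ReactionKind.BIMOLECULAR_S3, ReactionKind.BIMOLECULAR_S4):
                a_sp, b_sp = rxn.substrates[1], rxn.substrates[0]
            else:
                a_sp, b_sp = rxn.substrates
            for sp in (a_sp, b_sp):
                if sp not in species:
                    species.append(sp)
                if sp not in substrates:
                    substrates.append(sp)
            a1, d1 = rates["a1"], rates["d1"]
            a2, d2 = rates["a2"], rates["d2"]
            sb = f"S{tag}^b"
            cb = f"C{tag}^b"
            species += [sb, cb]
            r_complexes.append(cb)
            release = (product, a_sp, b_sp, R)
            if kind in (ReactionKind.BIMOLECULAR_S1, ReactionKind.BIMOLECULAR_S3):
                # substrates dimerize first, resource binds the dimer
                elem += [
                    ElementaryReaction((a_sp, b_sp), (sb,), a1 / epsilon, f"dim{tag}"),
                    ElementaryReaction((sb,), (a_sp, b_sp), d1 / epsilon, f"undim{tag}"),
                    ElementaryReaction((sb, R), (cb,), a2 / epsilon, f"bind{tag}"),
                    ElementaryReaction((cb,), (sb, R), d2 / epsilon, f"unbind{tag}"),
                    ElementaryReaction((cb,), release, kcat, f"cat{tag}"),
                ]
                k1 = a1 / d1
                k2 = a2 / (d2 + epsilon * kcat)
                induced.append(
                    CompetitiveReaction(
                        kind, kcat * k1 * k2, rxn.substrates, product,
                        pool.pool_id, w_ab=k1 * k2 / scale,
                    )
                )
            else:
                # resource binds the first substrate, partner binds the complex
                r_complexes.append(sb)
                elem += [
                    ElementaryReaction((a_sp, R), (sb,), a1 / epsilon, f"seed{tag}"),
                    ElementaryReaction((sb,), (a_sp, R), d1 / epsilon, f"unseed{tag}"),
                    ElementaryReaction((sb, b_sp), (cb,), a2 / epsilon, f"bind{tag}"),
                    ElementaryReaction((cb,), (sb, b_sp), d2 / epsilon, f"unbind{tag}"),
                    ElementaryReaction((cb,), release, kcat, f"cat{tag}"),
                ]
                k1 = a1 / d1
                k2 = a2 / (d2 + epsilon * kcat)
                wa = k1 / scale
                wab = k1 * k2 / scale
                subs = rxn.substrates
                if kind is ReactionKind.BIMOLECULAR_S4:
                    # w_a attaches to the resource-seeding substrate, which is
                    # substrates[1] under the mirror convention
                    subs = (rxn.substrates[1], rxn.substrates[0])
                induced.append(
                    CompetitiveReaction(
                        kind if kind is not ReactionKind.BIMOLECULAR_S4 else kind,
                        kcat * k1 * k2, subs, product, pool.pool_id,
                        w_ab=wab, w_a=wa,
                    )
                )
        else:  # pragma: no cover - enum is closed
            raise ConfigurationError(f"unsupported reaction kind {kind}")

    return MassActionExpansion(
        pool=induced_pool,
        species=species,
        reactions=elem,
        epsilon=epsilon,
        resource_species=R,
        resource_complexes=r_complexes,
        substrate_species=substrates,
        induced=induced,
    )


def reduced_product_trajectory(
    pool: ResourcePool,
    reactions: Sequence[CompetitiveReaction],
    substrate_concs: Mapping[str, float],
    times: np.ndarray,
) -> dict[str, np.ndarray]:
    """Reduced-model product time courses at fixed substrate levels.

    With substrates buffered, the free resource is constant and each product
    accumulates linearly at its reduced rate; used as the analytic half of
    the oracle-equivalence checks.
    """
    r = free_resource_concentration(pool, reactions, substrate_concs)
    out: dict[str, np.ndarray] = {}
    for rxn in reactions:
        v = production_rate(rxn, substrate_concs, r)
        out[rxn.product] = out.get(rxn.product, 0.0) + v * np.asarray(times, float)
    out["__r__"] = np.full(len(times), r)
    return out
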