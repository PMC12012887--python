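"""Reduced resource-competition rate laws and their mass-action expansion."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp

from relic.errors import ConfigurationError, InputError
from relic.oracle import compare_network, random_network
from relic.resources import (
    CompetitiveReaction,
    ReactionKind,
    ResourcePool,
    expand_to_mass_action,
    free_resource_concentration,
    production_rate,
)


def uni(w=1.0, beta=1.0, s="S", pool="pool"):
    return CompetitiveReaction(ReactionKind.UNIMOLECULAR, beta, (s,), "P",
                               pool, w_u=w)


class TestFreeResource:
    def test_no_competition_returns_full_capacity(self, pool100):
        assert free_resource_concentration(pool100, [], {}) == 100.0

    def test_single_unimolecular_competitor_halves_capacity(self, pool100):
        r = free_resource_concentration(pool100, [uni(w=1.0)], {"S": 1.0})
        assert r == pytest.approx(50.0)

    def test_zeroth_order_load_rescales_capacity(self):
        # nominal load Q0 = 1e-3 of the embedded-control case study
        pool = ResourcePool("pool", R_tot=100.0, Q0=1e-3)
        r = free_resource_concentration(pool, [], {})
        assert r == pytest.approx(100.0 / 1.001, rel=1e-12)

    def test_bimolecular_terms_enter_denominator(self, pool100):
        rxn = CompetitiveReaction(ReactionKind.BIMOLECULAR_S2, 1.0, ("A", "B"),
                                  "P", "pool", w_ab=0.5, w_a=0.25)
        r = free_resource_concentration(pool100, [rxn], {"A": 2.0, "B": 1.0})
        assert r == pytest.approx(100.0 / (1.0 + 0.5 * 2 + 0.25 * 2))

    def test_negative_concentration_rejected(self, pool100):
        with pytest.raises(InputError):
            free_resource_concentration(pool100, [uni()], {"S": -1.0})

    def test_foreign_pool_rejected(self, pool100):
        with pytest.raises(ConfigurationError):
            free_resource_concentration(pool100, [uni(pool="other")], {"S": 1.0})

    def test_w_a_is_structurally_zero_for_scenarios_1_and_3(self):
        for kind in (ReactionKind.BIMOLECULAR_S1, ReactionKind.BIMOLECULAR_S3):
            with pytest.raises(ConfigurationError):
                CompetitiveReaction(kind, 1.0, ("A", "B"), "P", "pool",
                                    w_ab=1.0, w_a=0.1)

    @settings(derandomize=True, max_examples=50)
    @given(
        s=st.floats(0.01, 50.0), w=st.floats(0.01, 5.0),
        R=st.floats(0.1, 500.0), bump=st.floats(0.01, 5.0),
    )
    def test_monotonicity_in_substrate_gain_and_capacity(self, s, w, R, bump):
        """r strictly decreases in substrate and gain, increases in R_tot."""
        def r(R_tot, wu, conc):
            pool = ResourcePool("pool", R_tot)
            return free_resource_concentration(pool, [uni(w=wu)], {"S": conc})

        base = r(R, w, s)
        assert r(R, w, s + bump) < base
        assert r(R, w + bump, s) < base
        assert r(R + bump, w, s) > base
        assert 0 < base <= R

    def test_gains_to_zero_recovers_unlimited_regime(self, pool100):
        """As all competition gains vanish, r -> R_eff."""
        for lam in (1.0, 1e-2, 1e-6):
            r = free_resource_concentration(
                pool100, [uni(w=lam), uni(w=2 * lam, s="S2")],
                {"S": 3.0, "S2": 1.0})
            assert abs(r - 100.0) <= 100.0 * 5 * lam
        r = free_resource_concentration(pool100, [uni(w=0.0)], {"S": 3.0})
        assert r == 100.0


class TestProductionRate:
    def test_unimolecular_rate_is_product_of_factors(self):
        assert production_rate(uni(beta=2.0), {"S": 3.0}, 0.5) == pytest.approx(3.0)

    def test_zero_substrate_gives_zero_bimolecular_rate(self):
        rxn = CompetitiveReaction(ReactionKind.BIMOLECULAR_S1, 5.0, ("A", "B"),
                                  "P", "pool", w_ab=1.0)
        assert production_rate(rxn, {"A": 0.0, "B": 7.0}, 3.0) == 0.0

    def test_zeroth_order_rate_is_identity_on_r(self):
        rxn = CompetitiveReaction(ReactionKind.ZEROTH, 1.0, (), "P", "pool")
        assert production_rate(rxn, {}, 99.9) == pytest.approx(99.9)

    def test_missing_substrate_concentration_rejected(self):
        with pytest.raises(InputError):
            production_rate(uni(), {}, 1.0)


class TestMassActionExpansion:
    def test_smallest_expansion_structure(self, pool100):
        """One unimolecular reaction: species {S, R, C, P}, 3 elementary steps."""
        exp = expand_to_mass_action(
            pool100, [uni()], {0: {"a": 1.0, "d": 1.0, "kcat": 1.0}}, epsilon=1e-2)
        assert len(exp.reactions) == 3
        assert len(exp.species) == 4  # R, P, S, C
        assert exp.resource_complexes == ["C0^u"]

    def test_epsilon_must_be_positive(self, pool100):
        with pytest.raises(InputError):
            expand_to_mass_action(pool100, [uni()],
                                  {0: {"a": 1, "d": 1, "kcat": 1}}, epsilon=0.0)

    def test_bimolecular_scenario1_releases_resource_on_catalysis(self, pool100):
        rxn = CompetitiveReaction(ReactionKind.BIMOLECULAR_S1, 1.0, ("A", "B"),
                                  "P", "pool", w_ab=1.0)
        exp = expand_to_mass_action(
            pool100, [rxn],
            {0: {"a1": 1, "d1": 1, "a2": 1, "d2": 1, "kcat": 1}}, epsilon=1e-2)
        cat = [r for r in exp.reactions if r.label == "cat0"][0]
        assert exp.resource_species in cat.products  # R released with product
        assert set(("A", "B")) <= set(cat.products)  # catalytic substrates recovered
        # scenario 1 sequesters resource only in the ternary complex
        assert exp.resource_complexes == ["C0^b"]
        assert exp.induced[0].w_a == 0.0

    def test_induced_gains_follow_qssa_lumping(self):
        """w = a/(d + eps*kcat) / (1+Q0); zeroth loads fold into Q0."""
        pool = ResourcePool("pool", 50.0)
        rxns = [
            CompetitiveReaction(ReactionKind.ZEROTH, 1.0, (), "P0", "pool"),
            uni(s="S1"),
        ]
        eps = 1e-3
        exp = expand_to_mass_action(
            pool, rxns,
            {0: {"a": 2.0, "d": 4.0, "kcat": 1.0},
             1: {"a": 3.0, "d": 2.0, "kcat": 0.5}}, epsilon=eps)
        q0 = 2.0 / (4.0 + eps * 1.0)
        assert exp.pool.Q0 == pytest.approx(q0)
        ahat = 3.0 / (2.0 + eps * 0.5)
        assert exp.induced[1].w_u == pytest.approx(ahat / (1 + q0))
        assert exp.induced[1].beta_star == pytest.approx(0.5 * ahat)

    def test_total_resource_conserved_with_dynamic_substrates(self, pool100):
        exp = expand_to_mass_action(
            pool100, [uni(), uni(s="S2")],
            {0: {"a": 0.5, "d": 1.0, "kcat": 1.0},
             1: {"a": 0.2, "d": 1.0, "kcat": 2.0}}, epsilon=1e-2)
        exp.buffered_substrates = False
        y0 = exp.initial_state({"S": 5.0, "S2": 3.0})
        sol = solve_ivp(exp.rhs, (0, 5.0), y0, method="LSODA",
                        rtol=1e-10, atol=1e-12, t_eval=np.linspace(0, 5, 30))
        totals = [exp.resource_total(sol.y[:, k]) for k in range(sol.t.size)]
        assert np.max(np.abs(np.array(totals) - 100.0)) / 100.0 < 1e-8

    def test_free_resource_converges_to_reduced_formula_as_eps_shrinks(self):
        """Two unimolecular reactions sharing R: sup-norm error decreases in eps."""
        pool = ResourcePool("pool", 0.2)
        rxns = [uni(s="S1"), uni(s="S2")]
        rates = {0: {"a": 0.2, "d": 1.0, "kcat": 1.0},
                 1: {"a": 0.1, "d": 1.0, "kcat": 0.5}}
        concs = {"S1": 1.0, "S2": 2.0}
        errs = [compare_network(pool, rxns, rates, concs, eps).sup_error
                for eps in (1.0, 1e-1, 1e-3)]
        assert errs[0] > errs[1] > errs[2]
        assert errs[2] < 0.02

    def test_random_small_networks_match_reduced_model(self):
        """Oracle equivalence on a handful of random networks at eps = 1e-3."""
        rng = np.random.default_rng(7)
        for _ in range(5):
            pool, rxns, rates, concs = random_network(rng)
            cmp = compare_network(pool, rxns, rates, concs, 1e-3)
            assert cmp.sup_error < 0.02
            assert cmp.conservation_error < 1e-8
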