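"""Embedded gene-expression control and the operon gene-ratio circuit."""

import numpy as np
import pytest

from relic.errors import ConfigurationError, DomainError
from relic.intracellular import (
    ExternalLoadSpec,
    GeneExpressionPlantParams,
    OperonCircuitParams,
    embedded_control_circuit,
    feasibility_conditions,
    layered_equilibrium,
    layered_gene_expression_circuit,
    operon_open_loop_ratio,
    operon_ratio_circuit,
    stability_criterion,
)
from relic.motifs import LayeredMotifParams, layered_setpoint
from relic.resources import ResourcePool
from relic.simulate import DisturbanceEvent, simulate, steady_state
from relic.stability import adaptation_error, find_positive_equilibrium


REF_CTRL = LayeredMotifParams(alpha1_star=1.0, alpha2_star=0.25, gamma_c2=0.25,
                              sense_gain=1.0, k_star=1.0, w1=1.0, w2=1.0)
REF_PLANT = GeneExpressionPlantParams(b_p1_star=0.1, gamma_p1=1.0, k_star=1.0)


class TestEmbeddedControl:
    def test_no_loads_reduces_to_layered_loop(self):
        bare = layered_gene_expression_circuit()
        loaded = embedded_control_circuit(
            REF_PLANT, ExternalLoadSpec(L=0), REF_CTRL,
            ResourcePool("pool", 100.0))
        y0 = bare.state_vector({"x1": 0.0, "z1": 0.1, "z2": 50.0})
        ta = simulate(bare, y0, 30.0)
        tb = simulate(loaded, y0, 30.0)
        assert np.allclose(ta.states, tb.states, rtol=1e-10, atol=1e-12)

    def test_nominal_load_matches_adjusted_effective_capacity(self):
        """A Q0 load equals rescaling R_tot and the competition gains."""
        q0 = 1e-3
        loaded = layered_gene_expression_circuit(Q0=q0)
        rescaled = layered_gene_expression_circuit(
            Q0=0.0, R_tot=100.0 / (1 + q0),
            w1=1.0 / (1 + q0), w2=1.0 / (1 + q0))
        y0 = loaded.state_vector({"x1": 0.0, "z1": 0.1, "z2": 50.0})
        ta = simulate(loaded, y0, 30.0)
        tb = simulate(rescaled, y0, 30.0)
        assert np.allclose(ta.states, tb.states, rtol=1e-9, atol=1e-11)

    def test_tenfold_load_step_is_rejected(self):
        m = layered_gene_expression_circuit(Q0=1e-3)
        y0 = m.state_vector({"x1": 0.0, "z1": 0.1, "z2": 50.0})
        pre = steady_state(m, y0)
        post = steady_state(m, pre.state, params={**m.params, "Q0": 1e-2})
        assert pre.converged and post.converged
        e_p = adaptation_error(pre.state[0], post.state[0])
        assert e_p == pytest.approx(1.0, abs=1e-6)


class TestFeasibility:
    def test_reference_parameterization_is_feasible(self):
        c1, c2 = feasibility_conditions(REF_PLANT, REF_CTRL,
                                        ResourcePool("pool", 100.0, 1e-3))
        assert c1 and c2
        assert layered_equilibrium(Q0=1e-3)["feasible"]

    def test_large_actuation_limit_reduces_to_capacity_bound(self):
        """As k* grows the second condition approaches R_tot > r*."""
        sp = layered_setpoint(REF_CTRL)
        ctrl_fast = LayeredMotifParams(
            alpha1_star=1.0, alpha2_star=0.25, gamma_c2=0.25, sense_gain=1.0,
            k_star=1e9, w1=1.0, w2=1.0)
        # capacity barely above r*: feasible only in the large-k* limit
        pool = ResourcePool("pool", sp.r_star * 1.01)
        assert feasibility_conditions(REF_PLANT, ctrl_fast, pool)[1]
        assert not feasibility_conditions(REF_PLANT, REF_CTRL, pool)[1]

    def test_violating_first_condition_leaves_no_positive_root(self):
        """With basal expression overshooting the set-point, z1* <= 0 and no
        strictly positive equilibrium exists (checked by root search)."""
        params = dict(b_p1_star=2.0)  # gamma_p1 * alpha2* * Sigma^2 = 0.25 < 0.5
        plant = GeneExpressionPlantParams(b_p1_star=2.0, gamma_p1=1.0, k_star=1.0)
        assert not feasibility_conditions(plant, REF_CTRL,
                                          ResourcePool("pool", 100.0))[0]
        assert not layered_equilibrium(**params)["feasible"]
        m = layered_gene_expression_circuit(**params)
        rep = find_positive_equilibrium(m, {"x1": 0.5, "z1": 0.5, "z2": 20.0})
        assert not (rep.found and rep.positivity)


class TestStabilityCriterion:
    def test_boundary_choice_satisfies_criterion(self):
        # gamma_c2 = gamma_p1 / 2 sits exactly on the sufficient boundary
        plant = GeneExpressionPlantParams(0.1, gamma_p1=0.5, k_star=1.0)
        assert stability_criterion(plant, REF_CTRL)

    def test_equal_rates_fail_criterion(self):
        plant = GeneExpressionPlantParams(0.1, gamma_p1=0.25, k_star=1.0)
        assert not stability_criterion(plant, REF_CTRL)

    def test_criterion_implies_numerical_stability_on_samples(self):
        """Feasible + criterion => all eigenvalues in the left half plane
        (spot check; the full 1000-sample sweep runs in the acceptance suite)."""
        from relic.fixtures import generate_fixture
        from relic.stability import numerical_jacobian
        for seed in range(20):
            cfg, _ = generate_fixture("layered_gene_expression", seed=seed,
                                      constraints=("stable_layered",))
            eq = layered_equilibrium(cfg.parameters)
            m = layered_gene_expression_circuit(**cfg.parameters)
            y = np.array([eq["x1"], eq["z1"], eq["z2"]])
            J = numerical_jacobian(lambda yy: m.rhs(0.0, yy, m.params), y)
            assert np.linalg.eigvals(J).real.max() < 0


class TestOperonCircuit:
    @staticmethod
    def start(m):
        return m.state_vector({"m_p": 0.1, "m_a": 0.0, "x1": 0.1, "x2": 0.1,
                               "z1": 0.1, "z2": 1.0})

    def test_open_loop_ratio_formula(self):
        assert operon_open_loop_ratio(1.0, 1.0, 1.0, 1.0) == 1.0
        assert operon_open_loop_ratio(1.0, 1.0, 1.0, 2.0) == 2.0
        assert operon_open_loop_ratio(2.0, 1.0, 0.5, 1.0) == 4.0
        with pytest.raises(DomainError):
            operon_open_loop_ratio(1.0, 1.0, 0.0, 1.0)

    def test_open_loop_simulation_matches_formula(self):
        """With the controller absent the simulated ratio equals
        eta1* gamma_x2 / (eta2* gamma_x1)."""
        m = operon_ratio_circuit(eta1_star=1.3, gamma_x2=0.7)
        y0 = m.state_vector({"m_p": 0.1, "x1": 0.1, "x2": 0.1})  # z1 = z2 = 0
        ss = steady_state(m, y0)
        assert ss.converged
        expected = operon_open_loop_ratio(1.3, 1.0, 1.0, 0.7)
        assert ss.state[2] / ss.state[3] == pytest.approx(expected, rel=1e-6)

    def test_closed_loop_ratio_invariant_across_gamma_x2(self):
        ratios, products = [], []
        for gx2 in (0.4, 0.6, 0.8, 1.0):
            m = operon_ratio_circuit(gamma_x2=gx2)
            ss = steady_state(m, self.start(m))
            assert ss.converged
            ratios.append(ss.state[2] / ss.state[3])
            r1 = m.derived["r1"](ss.state, m.params)
            r2 = m.derived["r2"](ss.state, m.params)
            products.append(r1 * r2)
        cv = np.std(ratios) / np.mean(ratios)
        assert cv <= 1e-3
        # the controller pins the product of the two free resource levels
        assert np.ptp(products) / np.mean(products) < 1e-6

    def test_symmetric_genes_with_unit_ratio_equalize(self):
        """With symmetric genes and a commanded ratio of one, the two protein
        levels converge to the same value (the actuation leg idles)."""
        m = operon_ratio_circuit(alpha2_star=1.0, gamma_c2=1.0,
                                 sense_gain=1.0, alpha1_star=1.0)
        y0 = m.state_vector({"m_p": 0.1, "x1": 0.2, "x2": 0.2,
                             "z1": 0.1, "z2": 1.0})
        ss = steady_state(m, y0)
        assert ss.converged
        assert ss.state[2] == pytest.approx(ss.state[3], rel=1e-4)

    def test_both_proteins_read_the_same_transcript(self):
        """Structural check: perturbing m_p changes both protein production
        terms identically (transcript identity)."""
        m = operon_ratio_circuit()
        y = m.state_vector({"m_p": 1.0, "x1": 0.5, "x2": 0.5,
                            "z1": 0.1, "z2": 1.0})
        base = m.rhs(0.0, y, m.params)
        y2 = y.copy()
        y2[m.index("m_p")] *= 2.0
        bumped = m.rhs(0.0, y2, m.params)
        r2b = m.derived["r2"](y2, m.params)
        gain_x1 = (bumped[m.index("x1")] - base[m.index("x1")])
        gain_x2 = (bumped[m.index("x2")] - base[m.index("x2")])
        # equal eta => equal sensitivity of both genes to the shared transcript
        assert gain_x1 == pytest.approx(gain_x2, rel=1e-12)

    def test_mrna_qss_reduction_preserves_steady_ratio(self):
        full = operon_ratio_circuit(gamma_x2=0.6)
        red = operon_ratio_circuit(gamma_x2=0.6, mrna_qss=1.0)
        ss_f = steady_state(full, self.start(full))
        ss_r = steady_state(red, self.start(red))
        assert ss_f.converged and ss_r.converged
        assert ss_f.state[2] / ss_f.state[3] == pytest.approx(
            ss_r.state[2] / ss_r.state[3], rel=1e-6)

    def test_two_distinct_pools_required(self):
        with pytest.raises(ConfigurationError):
            OperonCircuitParams(pool_tx=ResourcePool("R", 10.0),
                                pool_tl=ResourcePool("R", 10.0))
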