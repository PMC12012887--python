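"""Controller motifs: absorbing states, set-points, ratio manifold."""

import math

import numpy as np
import pytest

from relic.errors import DomainError, InputError
from relic.fixtures import generate_fixture
from relic.intracellular import (
    layered_equilibrium,
    layered_gene_expression_circuit,
    minimal_gene_expression_circuit,
    ratiometric_gene_expression_circuit,
)
from relic.motifs import (
    LayeredMotifParams,
    MinimalMotifParams,
    RatiometricParams,
    ResponseFunction,
    layered_motif_rhs,
    layered_setpoint,
    manifold_residual,
    minimal_motif_rhs,
    ratio_manifold,
    ratio_setpoint_linear,
    ratiometric_rhs,
)
from relic.resources import ResourcePool
from relic.simulate import DisturbanceEvent, simulate, steady_state
from relic.stability import adaptation_error, find_positive_equilibrium


def expression_plant(b=0.1, gamma=1.0):
    def f(x, r, u):
        return np.array([b * r + u - gamma * x[0]])
    return f


class TestAbsorbingStates:
    def test_minimal_z1_zero_is_absorbing(self, pool100):
        params = MinimalMotifParams(1.0, 1.0, 1.0, w_z1=1.0)
        dy = minimal_motif_rhs([0.0, 3.0], params, pool100, expression_plant())
        assert dy[0] == 0.0

    def test_layered_z_axes_are_absorbing(self, pool100):
        params = LayeredMotifParams(1.0, 0.25, 0.25, 1.0, 1.0, w1=1.0, w2=1.0)
        dy = layered_motif_rhs([0.0, 0.0, 2.0], params, pool100, expression_plant())
        assert dy[0] == 0.0 and dy[1] == 0.0
        dy = layered_motif_rhs([0.5, 0.0, 2.0], params, pool100, expression_plant())
        assert dy[1] == 0.0 and dy[0] != 0.0

    def test_ratiometric_controller_zeros_are_absorbing(self, pool100):
        params = RatiometricParams(1.0, 0.5, 1.0, 0.5, 1.0)
        def plant(x, r, u):
            return u - 0.1 * x
        dy = ratiometric_rhs([0.0, 0.0, 1.0, 2.0], params, pool100, plant)
        assert dy[0] == 0.0 and dy[1] == 0.0

    def test_positive_controller_stays_positive_along_trajectory(
            self, layered_model, layered_start):
        traj = simulate(layered_model, layered_start, 50.0)
        assert np.all(traj["z1"] > 0)
        assert np.all(traj["z2"] > 0)


class TestLayeredSetpoint:
    def test_resource_output_product_is_gamma_over_alpha(self):
        # printed reference parameterization: gamma_c2 = alpha2* = 0.25
        sp = layered_setpoint(LayeredMotifParams(1.0, 0.25, 0.25, 1.0, 1.0))
        assert sp.r_star * sp.sigma == pytest.approx(1.0, abs=1e-12)

    def test_ratio_tuning_rescales_r_star_at_fixed_sigma(self):
        """Raising gamma_c2/alpha2* by 3 while compensating alpha1* so that
        alpha1* gamma_c2 / alpha2* stays fixed keeps Sigma and triples r*."""
        base = layered_setpoint(LayeredMotifParams(1.0, 0.25, 0.25, 1.0, 1.0))
        scaled = layered_setpoint(LayeredMotifParams(1 / 3, 0.25, 0.75, 1.0, 1.0))
        assert scaled.sigma == pytest.approx(base.sigma)
        assert scaled.r_star == pytest.approx(3.0 * base.r_star)

    def test_sigma_invariant_to_process_and_resource_parameters(self):
        """Sigma depends on controller parameters only."""
        ctrl = dict(alpha1_star=0.7, alpha2_star=0.2, gamma_c2=0.1,
                    sense_gain=1.3, k_star=2.0)
        sigmas = {
            layered_setpoint(LayeredMotifParams(**ctrl, w1=w1, w2=w2)).sigma
            for w1 in (0.0, 5.0) for w2 in (0.0, 5.0)
        }
        assert len(sigmas) == 1

    def test_simulated_steady_state_satisfies_z2_balance(self):
        """At equilibrium alpha2* x1* r* = gamma_c2 (root-found numerically)."""
        m = layered_gene_expression_circuit()
        rep = find_positive_equilibrium(
            m, {"x1": 0.5, "z1": 0.5, "z2": 20.0})
        assert rep.found and rep.positivity
        x1 = rep.value(m, "x1")
        r = m.derived["r"](rep.state, m.params)
        p = m.params
        assert p["alpha2_star"] * x1 * r == pytest.approx(p["gamma_c2"], abs=1e-8)

    @pytest.mark.parametrize("seed", range(5))
    def test_sigma_matches_long_horizon_simulation(self, seed):
        cfg, _ = generate_fixture("layered_gene_expression", seed=seed,
                                  constraints=("stable_layered",))
        m = layered_gene_expression_circuit(**cfg.parameters)
        p = cfg.parameters
        sp = layered_setpoint(LayeredMotifParams(
            p["alpha1_star"], p["alpha2_star"], p["gamma_c2"],
            p["sense_gain"], p["k_star"], p["w1"], p["w2"]))
        eq = layered_equilibrium(p)
        y0 = m.state_vector({"x1": 0.0, "z1": 0.1,
                             "z2": max(1.0, 0.5 * eq["z2"])})
        ss = steady_state(m, y0)
        assert ss.converged
        assert ss.value(m, "x1") == pytest.approx(sp.sigma, rel=1e-4)


class TestMinimalMotifAdaptation:
    def test_without_competition_step_is_perfectly_rejected(self):
        m = minimal_gene_expression_circuit(w_z1=0.0, w_bar_lin=0.0, w_bar_quad=0.0)
        y0 = m.state_vector({"x1": 0.0, "z1": 0.1})
        pre = steady_state(m, y0).value(m, "x1")
        post = steady_state(m, y0, params={**m.params, "k_star": 1.2}).value(m, "x1")
        assert adaptation_error(pre, post) == pytest.approx(1.0, abs=1e-6)

    def test_with_competition_step_leaves_residual_error(self):
        m = minimal_gene_expression_circuit()
        y0 = m.state_vector({"x1": 0.0, "z1": 0.1})
        pre = steady_state(m, y0).value(m, "x1")
        post = steady_state(m, y0, params={**m.params, "k_star": 1.2}).value(m, "x1")
        assert abs(adaptation_error(pre, post) - 1.0) > 0.01


class TestRatioManifold:
    def test_symmetric_linear_parameters_give_identity_map(self):
        params = RatiometricParams(1.0, 1.0, 1.0, 1.0, 1.0)
        assert ratio_setpoint_linear(params) == pytest.approx(1.0)
        assert ratio_manifold(params, 3.7) == pytest.approx(3.7)

    def test_linear_manifold_is_homogeneous(self):
        params = RatiometricParams(2.0, 0.5, 1.0, 0.4, 1.0)
        x2 = 1.3
        assert ratio_manifold(params, 2 * x2) == pytest.approx(
            2 * ratio_manifold(params, x2), rel=1e-12)

    def test_hill_manifold_slope_at_origin_matches_linear_limit(self):
        """Monotone nonlinear manifold; origin slope equals the linear formula
        with each map replaced by its initial slope."""
        H1 = ResponseFunction("hill", gain=2.0, ec50=1.5)
        G2 = ResponseFunction("hill", gain=3.0, ec50=2.0)
        params = RatiometricParams(1.0, 0.5, 1.0, 0.5, 1.0, H1=H1, G2=G2)
        lin = RatiometricParams(
            1.0, 0.5, 1.0, 0.5, 1.0,
            H1=ResponseFunction("linear", H1.slope0),
            G2=ResponseFunction("linear", G2.slope0))
        expected = ratio_setpoint_linear(lin)
        h = 1e-5
        slope = ratio_manifold(params, h) / h
        assert slope == pytest.approx(expected, rel=1e-3)
        # monotone but nonlinear away from the origin
        xs = [0.5, 1.0, 2.0]
        ys = [ratio_manifold(params, x) for x in xs]
        assert ys[0] < ys[1] < ys[2]
        assert ys[2] / xs[2] != pytest.approx(ys[0] / xs[0], rel=1e-3)

    def test_saturating_target_outside_range_raises(self):
        params = RatiometricParams(
            5.0, 0.5, 5.0, 0.5, 1.0,
            H1=ResponseFunction("hill", gain=1.0, ec50=1.0),
            H2=ResponseFunction("hill", gain=1.0, ec50=1.0))
        with pytest.raises(DomainError):
            ratio_manifold(params, 100.0)

    def test_linear_setpoint_rejects_hill_tags(self):
        params = RatiometricParams(
            1.0, 0.5, 1.0, 0.5, 1.0, H1=ResponseFunction("hill"))
        with pytest.raises(InputError):
            ratio_setpoint_linear(params)

    def test_nonpositive_x2_rejected(self):
        with pytest.raises(InputError):
            ratio_manifold(RatiometricParams(1.0, 0.5, 1.0, 0.5, 1.0), 0.0)


class TestRatiometricClosedLoop:
    @pytest.mark.parametrize("seed", range(5))
    def test_linear_gamma_matches_simulated_ratio(self, seed):
        cfg, _ = generate_fixture("ratiometric_gene_expression", seed=seed,
                                  constraints=("stable_numeric",))
        m = ratiometric_gene_expression_circuit(**cfg.parameters)
        p = cfg.parameters
        gamma = ratio_setpoint_linear(RatiometricParams(
            p["alpha1_star"], p["alpha2_star"], p["gamma_c2"],
            p["sense_gain"], p["k_star"]))
        ss = steady_state(m, m.state_vector(
            {"x1": 0.1, "x2": 0.1, "z1": 0.1, "z2": 1.0}))
        assert ss.converged
        assert ss.state[0] / ss.state[1] == pytest.approx(gamma, rel=1e-6)

    def test_steady_state_sits_on_manifold_with_hill_maps(self):
        H1 = ResponseFunction("hill", gain=4.0, ec50=3.0)
        m = ratiometric_gene_expression_circuit(H1=H1)
        ss = steady_state(m, m.state_vector(
            {"x1": 0.1, "x2": 0.1, "z1": 0.1, "z2": 1.0}))
        assert ss.converged
        params = RatiometricParams(
            m.params["alpha1_star"], m.params["alpha2_star"],
            m.params["gamma_c2"], m.params["sense_gain"], m.params["k_star"],
            H1=H1)
        res = manifold_residual(params, ss.state[0], ss.state[1])
        scale = params.manifold_constant * params.G1(ss.state[1]) * params.G2(ss.state[1])
        assert abs(res) / scale < 1e-6

    def test_gamma_robust_to_process_degradation_rates(self):
        """Closed-loop ratio invariant to gamma_x perturbations."""
        ratios = []
        for gx2 in (0.5, 1.0, 2.0):
            m = ratiometric_gene_expression_circuit(gamma_x2=gx2)
            ss = steady_state(m, m.state_vector(
                {"x1": 0.1, "x2": 0.1, "z1": 0.1, "z2": 1.0}))
            assert ss.converged
            ratios.append(ss.state[0] / ss.state[1])
        assert np.ptp(ratios) / np.mean(ratios) < 1e-6
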