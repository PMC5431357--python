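"""The deterministic system: spiral interior, sliding boundary, limit cycle."""

import math

import numpy as np
import pytest
import scipy.linalg

from loopwaves import (
    ModelParams,
    boundary_flow,
    boundary_generator,
    boundary_weight,
    integrate,
    interior_flow,
    interior_generator,
    kappa_b,
    kappa_e,
    limit_cycle,
    params_for_theta,
    theta_critical,
    wave_characteristics_curve,
)
from loopwaves.meanfield import SlidingExit, _spiral_states


class TestInteriorFlow:
    def test_centre_is_equilibrium(self, wave_params):
        assert np.allclose(interior_flow([400, 400, 400], wave_params), 0, atol=1e-10)

    def test_components_sum_to_zero(self, wave_params):
        flow = interior_flow([500, 300, 200], wave_params)
        assert flow.sum() == pytest.approx(0.0, abs=1e-10)

    def test_subcritical_flow_converges_to_centre(self):
        p = ModelParams(1, 1, 1.0)  # mu < 3r/2
        traj = integrate(p, [700.0, 200.0, 100.0], 60.0)
        assert traj.label == "amorphous"
        assert np.allclose(traj.m[-1], 1000 / 3, atol=1e-3)

    def test_closed_form_spiral_matches_matrix_exponential(self):
        # independent oracle: propagate with scipy's expm on B_interior
        rng = np.random.default_rng(3)
        for _ in range(10):
            p = ModelParams(
                r=rng.uniform(0.5, 2), rho=rng.uniform(0.1, 1), mu=rng.uniform(0, 3)
            )
            m0 = rng.uniform(0.5, 3.0, size=3)
            for t in (0.3, 1.1):
                exact = m0 @ scipy.linalg.expm(interior_generator(p) * t)
                spiral = _spiral_states(m0, p, [t])[0]
                assert np.allclose(spiral, exact, atol=1e-10)

    def test_spiral_rotation_and_growth_rates(self, wave_params):
        # deviation rotates at (sqrt(3)/2) r rho while growing at mu - 3r/2
        p = wave_params
        m0 = np.array([1 / 3 + 0.05, 1 / 3 - 0.025, 1 / 3 - 0.025])
        t_rot = 2 * math.pi / (math.sqrt(3) / 2 * p.r * p.rho)
        after = _spiral_states(m0, p, [t_rot])[0]
        growth = (after - 1 / 3) / (m0 - 1 / 3)
        assert np.allclose(growth, math.exp((p.mu - 1.5 * p.r) * t_rot), rtol=1e-8)


class TestBoundary:
    def test_weight_is_one_exactly_at_kappa_b(self):
        for theta in (0.3, 0.6, 0.9, 1.15):
            p = params_for_theta(theta)
            x = kappa_b(theta)
            m = np.array([x, 0.0, 1.0 - x])
            assert boundary_weight(m, p, empty_node=1) == pytest.approx(1.0)

    def test_weight_direct_evaluation(self):
        p = ModelParams(1, 1, 1.8)
        m = np.array([0.5, 0.0, 0.5])
        assert boundary_weight(m, p, 1) == pytest.approx(5 / 6)

    def test_weight_vanishes_when_lead_empty_under_full_bias(self):
        p = ModelParams(1, 1, 1.8)
        m = np.array([0.0, 0.0, 1.0])
        assert boundary_weight(m, p, 1) == pytest.approx(0.0)

    def test_weight_undefined_without_deaths(self):
        with pytest.raises(ValueError, match="mu = 0"):
            boundary_weight([0.5, 0, 0.5], ModelParams(1, 1, 0.0), 1)

    def test_sliding_rate_direct_evaluation(self):
        # theta = 0.6, r rho = 1, x = 0.6 -> dx/dt = 0.28
        p = params_for_theta(0.6)
        m = np.array([0.6, 0.0, 0.4])
        flow = boundary_flow(m, p, empty_node=1)
        assert flow[0] == pytest.approx(0.28)
        assert flow[1] == 0.0
        assert flow.sum() == pytest.approx(0.0, abs=1e-14)

    def test_equilibrium_at_kappa_e(self):
        theta = 1.3
        p = params_for_theta(theta)
        x = kappa_e(theta)
        flow = boundary_flow(np.array([x, 0.0, 1.0 - x]), p, 1)
        assert np.allclose(flow, 0.0, atol=1e-14)

    def test_sliding_flow_equals_filippov_blend(self):
        # w-weighted combination of interior and boundary generators must
        # reproduce the scalar sliding law and pin the empty component
        rng = np.random.default_rng(7)
        for theta in (0.2, 0.6, 1.1):
            p = params_for_theta(theta)
            for _ in range(5):
                x = rng.uniform(0.05, kappa_b(theta) - 0.01)
                m = np.array([x, 0.0, 1.0 - x])
                w = boundary_weight(m, p, 1)
                blend = w * (m @ interior_generator(p)) + (1 - w) * (
                    m @ boundary_generator(p, 1)
                )
                assert blend[1] == pytest.approx(0.0, abs=1e-12)
                assert np.allclose(blend, boundary_flow(m, p, 1), atol=1e-12)

    def test_exit_signalled_above_kappa_b(self):
        theta = 0.6
        p = params_for_theta(theta)
        x = kappa_b(theta) + 0.05
        with pytest.raises(SlidingExit):
            boundary_flow(np.array([x, 0.0, 1.0 - x]), p, 1)


class TestThetaCritical:
    def test_value_and_residual(self):
        tc = theta_critical()
        assert round(tc, 4) == 1.2037
        x = tc / math.sqrt(3)
        assert abs(math.log(x) / x + math.pi / 6) <= 1e-8

    def test_sqrt_three_is_not_a_root(self):
        x = math.sqrt(3) / math.sqrt(3)
        assert math.log(x) / x + math.pi / 6 == pytest.approx(math.pi / 6)


class TestHybridIntegration:
    def test_regime_map_from_near_centre(self):
        m0 = [340.0, 330.0, 330.0]
        assert integrate(ModelParams(1, 1, 1.0), m0, 100).label == "amorphous"
        assert integrate(params_for_theta(0.6), m0, 100).label == "limit_cycle"
        assert integrate(params_for_theta(1.4), m0, 100).label == "collapsed"

    def test_simplex_conserved_across_region_switches(self):
        traj = integrate(params_for_theta(0.6), [340.0, 330.0, 330.0], 100)
        assert len(set(traj.region)) >= 2  # interior and boundary segments
        assert np.abs(traj.m.sum(axis=1) - 1000.0).max() <= 1e-9 * 1000
        assert traj.m.min() >= -1e-12

    def test_coexistence_window_depends_on_start(self):
        # 1 < theta < theta_c: wave from near the centre, collapse from a
        # boundary arrival below kappa_e
        p = params_for_theta(1.1)
        assert integrate(p, [335.0, 333.0, 332.0], 200).label == "limit_cycle"
        ke = kappa_e(1.1)
        low = 0.5 * ke  # arrival below the unstable boundary point
        assert integrate(p, [low * 999, 0.5, (1 - low) * 999], 200).label == "collapsed"

    def test_negative_bias_mirrors_the_flow(self):
        fwd = integrate(params_for_theta(0.6), [340.0, 330.0, 330.0], 60)
        bwd = integrate(
            ModelParams(1, -1, 1.8), np.array([340.0, 330.0, 330.0])[[0, 2, 1]], 60
        )
        assert bwd.label == fwd.label == "limit_cycle"


class TestLimitCycle:
    def test_wave_point_characteristics_are_consistent(self):
        wc = limit_cycle(params_for_theta(0.6))
        assert wc.exists
        assert wc.frequency == pytest.approx(1.0 / wc.period)
        assert wc.fhat == pytest.approx(wc.frequency)  # r rho = 1
        assert 1.0 < wc.amplitude < 3.0
        assert wc.diagnostics["x_departure"] == pytest.approx(kappa_b(0.6))

    def test_fhat_is_a_function_of_theta_alone(self):
        a = limit_cycle(params_for_theta(0.6, r=1.0, rho=1.0))
        b = limit_cycle(params_for_theta(0.6, r=2.0, rho=0.5))
        assert a.fhat == pytest.approx(b.fhat, rel=1e-6)
        assert a.amplitude == pytest.approx(b.amplitude, rel=1e-6)
        assert b.frequency == pytest.approx(a.frequency)  # r*rho = 1 in both

    def test_no_cycle_outside_wave_window(self):
        assert not limit_cycle(params_for_theta(-0.5)).exists
        assert not limit_cycle(params_for_theta(1.3)).exists
        tc = theta_critical()
        marginal = limit_cycle(params_for_theta(tc))
        assert not marginal.exists and marginal.marginal

    def test_cycle_matches_hybrid_integration_period(self):
        # independent check: time between boundary arrivals in integrate()
        p = params_for_theta(0.6)
        wc = limit_cycle(p)
        traj = integrate(p, [340.0, 330.0, 330.0], 200.0)
        assert traj.label == "limit_cycle"
        # once settled, successive boundary arrivals are one segment apart
        arrivals = []
        prev = None
        for t, r in zip(traj.times, traj.region):
            if r.startswith("boundary") and (prev is None or not prev.startswith("boundary")):
                arrivals.append(t)
            prev = r
        assert len(arrivals) >= 3
        seg = arrivals[-1] - arrivals[-2]
        assert seg == pytest.approx(wc.period / 3, rel=1e-6)

    def test_curve_monotonicity_and_existence_flags(self):
        table = wave_characteristics_curve([0.3, 0.6, 0.9, 1.3])
        assert list(table.exists) == [True, True, True, False]
        live = table[table.exists]
        assert np.all(np.diff(live.fhat) < 0)  # frequency falls with theta
        assert np.all(np.diff(live.amplitude) > 0)  # amplitude grows with theta
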