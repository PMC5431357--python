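"""Exactness and bookkeeping of the stochastic simulation engine."""

import numpy as np
import pytest

from loopwaves import (
    Extinct,
    ModelParams,
    SystemState,
    ensemble,
    gillespie_step,
    propensities,
    simulate,
)


class TestPropensities:
    def test_hand_enumerated_example(self):
        # state (2,1,0) with r=1, rho=1, mu=2: Z=2, n_tot=3
        p = ModelParams(r=1, rho=1, mu=2)
        props = propensities(SystemState(np.array([2, 1, 0])), p)
        assert np.allclose(props.forward, [2, 1, 0])
        assert np.allclose(props.backward, [0, 0, 0])
        assert np.allclose(props.birth, [4, 2, 0])
        assert np.allclose(props.death, [3, 3, 0])
        assert props.total == pytest.approx(15.0)

    @pytest.mark.parametrize("state", [[5, 0, 2], [1, 1, 1], [0, 7, 0], [3, 2, 9]])
    def test_total_birth_rate_equals_total_death_rate(self, state):
        p = ModelParams(r=0.7, rho=0.3, mu=1.3)
        props = propensities(SystemState(np.array(state)), p)
        assert props.birth.sum() == pytest.approx(props.death.sum())
        assert props.birth.sum() == pytest.approx(p.mu * sum(state))

    def test_pure_forward_bias_kills_backward_rates(self):
        p = ModelParams(r=1, rho=1, mu=0)
        props = propensities(SystemState(np.array([4, 0, 0])), p)
        assert props.backward.sum() == 0.0
        assert np.count_nonzero(props.forward) == 1

    def test_empty_system_has_zero_rates(self):
        props = propensities(SystemState(np.array([0, 0, 0])), ModelParams(1, 1, 2))
        assert props.total == 0.0


class TestGillespieStep:
    def test_single_particle_pure_forward_walk(self, rng):
        p = ModelParams(r=1, rho=1, mu=0)
        state = SystemState(np.array([1, 0, 0]))
        for _ in range(5):
            ev, state = gillespie_step(state, p, rng)
            assert ev.kind == "migrate_forward"
        assert state.n.sum() == 1
        assert state.n[(5) % 3] == 1  # five forward hops from node 0

    def test_empty_system_is_absorbed(self, rng):
        with pytest.raises(Extinct):
            gillespie_step(SystemState(np.array([0, 0, 0])), ModelParams(1, 1, 2), rng)

    def test_event_frequencies_match_propensity_fractions(self, rng):
        # repeated single steps from one fixed state: multinomial check at 4 sigma
        p = ModelParams(r=1, rho=0.5, mu=1.0)
        base = SystemState(np.array([3, 1, 0]))
        props = propensities(base, p)
        flat = props.flat()
        n_draws = 30000
        counts = np.zeros_like(flat)
        for _ in range(n_draws):
            ev, new = gillespie_step(base.copy(), p, rng)
            kind = {"migrate_forward": 0, "migrate_backward": 1, "birth": 2, "death": 3}
            counts[kind[ev.kind] * 3 + ev.node] += 1
        frac = flat / flat.sum()
        for k in range(len(flat)):
            sigma = np.sqrt(n_draws * frac[k] * (1 - frac[k]))
            assert abs(counts[k] - n_draws * frac[k]) <= 4 * max(sigma, 1.0)

    def test_waiting_time_uses_total_rate(self, rng):
        # mean of exponential waiting times ~ 1/total over many draws
        p = ModelParams(r=1, rho=0, mu=1.0)
        base = SystemState(np.array([2, 2, 2]))
        total = propensities(base, p).total
        dts = []
        for _ in range(20000):
            ev, new = gillespie_step(base.copy(), p, rng)
            dts.append(new.t)
        mean = np.mean(dts)
        assert abs(mean - 1 / total) < 4 * (1 / total) / np.sqrt(len(dts))


class TestSimulate:
    def test_migrations_conserve_total_when_mu_zero(self):
        p = ModelParams(r=1, rho=0.6, mu=0.0)
        traj = simulate(p, [40, 30, 20], 20.0, seed=7)
        assert np.all(traj.totals == 90)
        assert traj.status == "ok"

    def test_bit_reproducible_and_seed_sensitive(self, wave_params):
        a = simulate(wave_params, [100] * 3, 10.0, seed=3)
        b = simulate(wave_params, [100] * 3, 10.0, seed=3)
        c = simulate(wave_params, [100] * 3, 10.0, seed=4)
        assert np.array_equal(a.states, b.states)
        assert not np.array_equal(a.states, c.states)

    def test_python_and_kernel_engines_share_semantics(self, wave_params):
        # both engines: piecewise-constant grid sampling, non-negative states
        fast = simulate(wave_params, [50] * 3, 5.0, seed=11)
        slow = simulate(wave_params, [50] * 3, 5.0, seed=11, record_events=True)
        for traj in (fast, slow):
            assert np.all(traj.states >= 0)
            assert traj.sample_times[0] == 0.0
            assert np.all(traj.states[0] == 50)
        assert slow.events is not None and len(slow.events) > 0

    def test_event_log_invariants(self, wave_params):
        # strictly increasing times; deaths only at populated nodes;
        # migrations conserve, births/deaths change the total by exactly 1
        traj = simulate(wave_params, [20] * 3, 5.0, seed=1, record_events=True)
        state = np.array([20, 20, 20])
        last_t = 0.0
        for ev in traj.events:
            assert ev.t > last_t
            last_t = ev.t
            before = state.sum()
            if ev.kind == "migrate_forward":
                state[ev.node] -= 1
                state[(ev.node + 1) % 3] += 1
                assert state.sum() == before
            elif ev.kind == "migrate_backward":
                state[ev.node] -= 1
                state[(ev.node - 1) % 3] += 1
                assert state.sum() == before
            elif ev.kind == "birth":
                state[ev.node] += 1
                assert state.sum() == before + 1
            else:
                assert state[ev.node] > 0  # death cannot fire at an empty node
                state[ev.node] -= 1
                assert state.sum() == before - 1
            assert np.all(state >= 0)

    def test_extinction_truncates_and_flags(self):
        # tiny critical population dies out quickly at high mu
        p = ModelParams(r=1, rho=1, mu=5.0)
        hit = 0
        for seed in range(30):
            traj = simulate(p, [1, 0, 0], 50.0, seed=seed)
            if traj.status == "extinct":
                hit += 1
                assert traj.n_samples < 501
        assert hit > 20  # extinction is near-certain for a single particle

    def test_wave_state_oscillates_and_empties_nodes(self, wave_sim):
        frac = wave_sim.states / wave_sim.totals[:, None]
        assert frac.min() < 0.02  # nodes periodically empty...
        assert frac.max() > 0.6  # ...and refill to a dominant share

    def test_validates_inputs(self, wave_params):
        with pytest.raises(ValueError, match="length"):
            simulate(wave_params, [1, 2], 1.0, seed=0)
        with pytest.raises(ValueError, match="t_max"):
            simulate(wave_params, [1, 2, 3], -1.0, seed=0)


class TestEnsemble:
    def test_mean_total_conserved_within_standard_error(self):
        # the equal-rate birth-death total is a martingale
        p = ModelParams(r=1, rho=1, mu=1.0)
        res = ensemble(p, [20, 20, 20], n_reps=200, seed_base=50, t_max=1.0)
        totals_end = np.array([
            (t.states[-1].sum() if t.status == "ok" else 0) for t in res.trajectories
        ])
        se = totals_end.std(ddof=1) / np.sqrt(len(totals_end))
        assert abs(res.mean_total[-1] - 60.0) <= 3 * se

    def test_unbiased_no_birth_relaxes_to_uniform_thirds(self):
        p = ModelParams(r=1, rho=0, mu=0.0)
        res = ensemble(p, [90, 0, 0], n_reps=150, seed_base=9, t_max=12.0)
        per_node = res.mean[-1]
        sd = np.sqrt(res.var[-1] / 150)
        assert np.all(np.abs(per_node - 30.0) <= 4 * sd)

    def test_single_replicate_has_zero_variance(self, wave_params):
        res = ensemble(wave_params, [10] * 3, n_reps=1, seed_base=0, t_max=1.0)
        assert np.all(res.var == 0.0)

    def test_replicate_seeds_are_deterministic(self, wave_params):
        r1 = ensemble(wave_params, [30] * 3, n_reps=3, seed_base=100, t_max=2.0)
        direct = simulate(wave_params, [30] * 3, 2.0, seed=102)
        assert np.array_equal(r1.trajectories[2].states, direct.states)
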