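"""The environment process, trust updates, the five phases and full runs."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from hiersim import (
    global_reaching_centrality,
    AbilitySpec,
    ConfigError,
    Environment,
    SimConfig,
    Simulation,
    nomination_count,
    perceived_fitness,
    run_simulation,
    step_environment,
)
from hiersim.sim_core import accept, decide, nominate, relative_noise_at


class TestEnvironment:
    def test_never_flips_at_p_zero(self, rng):
        env = Environment(state=3)
        for _ in range(100):
            step_environment(env, 0.0, 5, rng)
        assert env.state == 3

    def test_forced_flip_excludes_current_state(self, rng):
        env = Environment(state=2)
        for _ in range(200):
            old = env.state
            step_environment(env, 1.0, 4, rng)
            assert env.state != old
            assert 1 <= env.state <= 4

    def test_flip_fraction_matches_p(self, rng):
        env = Environment(state=1)
        p, steps = 0.1, 10_000
        flips = 0
        for _ in range(steps):
            old = env.state
            step_environment(env, p, 5, rng)
            flips += env.state != old
        se = math.sqrt(p * (1 - p) / steps)
        assert abs(flips / steps - p) < 3 * se

    def test_requires_two_states(self, rng):
        with pytest.raises(ConfigError):
            step_environment(Environment(state=1), 0.5, 1, rng)


class TestPerceivedFitness:
    def test_prior_is_uniform_over_states(self):
        assert perceived_fitness(0, 0, 5) == pytest.approx(0.2)

    def test_matches_dirichlet_posterior_mean(self):
        """(s+1)/(n+l) is the posterior mean of a categorical success
        probability under a flat Dirichlet prior: marginally Beta(1, l-1)
        updated to Beta(1+s, l-1+n-s)."""
        for s, n, l in [(3, 4, 2), (0, 7, 5), (10, 12, 3)]:
            oracle = stats.beta(1 + s, l - 1 + n - s).mean()
            assert perceived_fitness(s, n, l) == pytest.approx(oracle)
        assert perceived_fitness(3, 4, 2) == pytest.approx(2 / 3)

    def test_perfect_record_tends_to_one(self):
        assert perceived_fitness(10_000, 10_000, 5) > 0.999

    @settings(max_examples=60, deadline=None)
    @given(n=st.integers(0, 200), l=st.integers(2, 10), data=st.data())
    def test_bounds_and_monotonicity(self, n, l, data):
        s = data.draw(st.integers(0, n))
        t = perceived_fitness(s, n, l)
        assert 0.0 < t < 1.0
        if s < n:
            assert perceived_fitness(s + 1, n, l) > t

    def test_contract_violation(self):
        with pytest.raises(ValueError):
            perceived_fitness(5, 4, 3)


class TestNominationCount:
    @pytest.mark.parametrize("a,k,expected", [
        (0.25, 3, 3),   # ceil(2.25)
        (1.0, 5, 0),    # perfectly fit agents ask no one
        (0.9, 3, 1),    # ceil(0.3)
        (0.5, 2, 1),    # exact integer product must not round up
        (1 / 3, 3, 2),
    ])
    def test_values(self, a, k, expected):
        assert nomination_count(a, k) == expected

    def test_rejects_bad_ability(self):
        with pytest.raises(ValueError):
            nomination_count(0.0, 3)


class TestNominate:
    def test_distinct_scores_give_argmax(self, rng):
        trust = np.array([0.5, 0.1, 0.9, 0.3, 0.7])
        primary, backup = nominate(0, trust, 2, rng)
        assert primary == [2, 4]
        assert backup == [3, 1]

    def test_symmetric_ties_break_uniformly(self):
        counts = {1: 0, 2: 0}
        rng = np.random.default_rng(0)
        trials = 4000
        for _ in range(trials):
            primary, _ = nominate(0, np.full(3, 0.2), 1, rng)
            counts[primary[0]] += 1
        se = math.sqrt(0.25 / trials)
        assert abs(counts[1] / trials - 0.5) < 4 * se

    def test_huge_noise_decorrelates_ranking(self, rng):
        trust = np.linspace(0.1, 0.9, 30)
        corrs = []
        for _ in range(300):
            primary, backup = nominate(0, trust, 14, rng, noise_sd=100 * 0.25)
            ranked = primary + backup
            corrs.append(stats.spearmanr(
                np.arange(len(ranked)), trust[ranked]).statistic)
        assert abs(np.mean(corrs)) < 0.05

    def test_truncates_to_available_candidates(self, rng):
        primary, backup = nominate(0, np.full(3, 0.2), 5, rng)
        assert len(primary) == 2 and backup == []


class TestAccept:
    def test_capacity_not_binding(self, rng):
        acc, rej = accept([1, 2, 3], set(), 5, rng)
        assert acc == {1, 2, 3} and rej == set()

    def test_zero_capacity_rejects_all(self, rng):
        acc, rej = accept([1, 2], set(), 0, rng)
        assert acc == set() and rej == {1, 2}

    def test_previous_partner_has_priority(self, rng):
        for _ in range(50):
            acc, rej = accept([7, 9], {9}, 1, rng)
            assert acc == {9} and rej == {7}

    def test_uniform_within_class(self):
        rng = np.random.default_rng(1)
        wins = 0
        trials = 4000
        for _ in range(trials):
            acc, _ = accept([1, 2], set(), 1, rng)
            wins += 1 in acc
        assert abs(wins / trials - 0.5) < 4 * math.sqrt(0.25 / trials)


class TestDecide:
    def test_no_messages_returns_own_guess(self, rng):
        assert decide(3, 0.4, [], 5, rng) == 3

    def test_trusted_provider_overrides_own_guess(self, rng):
        """Two-term weighted-plurality oracle: the provider wins exactly
        when its weight exceeds the agent's own."""
        assert decide(1, 0.3, [(2, 0.6)], 5, rng) == 2
        assert decide(1, 0.7, [(2, 0.6)], 5, rng) == 1

    def test_symmetric_tie_between_messages(self):
        rng = np.random.default_rng(2)
        counts = {1: 0, 2: 0}
        trials = 4000
        for _ in range(trials):
            counts[decide(3, 0.1, [(1, 0.4), (2, 0.4)], 5, rng)] += 1
        assert abs(counts[1] / trials - 0.5) < 4 * math.sqrt(0.25 / trials)


class TestConfigValidation:
    def test_valid_config_passes(self, tiny_config):
        tiny_config.validate()

    @pytest.mark.parametrize("field,value", [
        ("n", 0), ("l", 1), ("p", 1.5), ("p", -0.1), ("k", -1),
        ("capacity_low", 0), ("rounds", 0), ("half_life", 0.0),
    ])
    def test_invalid_fields_rejected(self, tiny_config, field, value):
        setattr(tiny_config, field, value)
        with pytest.raises(ConfigError):
            tiny_config.validate()

    def test_capacity_ordering(self, tiny_config):
        tiny_config.capacity_low, tiny_config.capacity_high = 5, 2
        with pytest.raises(ConfigError):
            tiny_config.validate()


def test_relative_noise_schedule_lookup():
    assert relative_noise_at(0.2, 123) == 0.2
    sched = {500: 0.4, 3500: 0.0}
    assert relative_noise_at(sched, 1) == 0.0
    assert relative_noise_at(sched, 500) == 0.4
    assert relative_noise_at(sched, 3499) == 0.4
    assert relative_noise_at(sched, 3500) == 0.0


class TestRoundInvariants:
    def test_capacity_budget_and_self_edges_every_round(self, tiny_config):
        sim = Simulation(tiny_config)
        budgets = sim.ask_budget
        received_total = np.zeros((tiny_config.n, tiny_config.n))
        for t in range(1, tiny_config.rounds + 1):
            snap = sim.run_round()
            if snap.m:
                providers, receivers = snap.edges[:, 0], snap.edges[:, 1]
                assert np.all(providers != receivers)
                out_deg = np.bincount(providers, minlength=tiny_config.n)
                assert np.all(out_deg <= sim.capacities)
                in_use = np.bincount(receivers, minlength=tiny_config.n)
                assert np.all(in_use <= budgets)
                if t > 1:
                    received_total[receivers, providers] += 1
            # trust bounds hold at all times
            trust = sim.trust_matrix()
            off = ~np.eye(tiny_config.n, dtype=bool)
            assert np.all((trust[off] > 0) & (trust[off] < 1))
            assert np.all(sim.counts_s <= sim.counts_n)
        # every transfer from round 2 on was counted exactly once
        assert np.array_equal(received_total, sim.counts_n)

    def test_trust_diagonal_is_own_ability(self, tiny_config):
        sim = Simulation(tiny_config)
        assert np.allclose(np.diag(sim.trust_matrix()), sim.abilities)

    def test_round_one_has_no_trust_updates(self, tiny_config):
        sim = Simulation(tiny_config)
        snap = sim.run_round()
        assert sim.counts_n.sum() == 0  # edges recorded, nothing propagated yet


class TestRunSimulation:
    def test_same_seed_bit_identical(self, tiny_config):
        a = run_simulation(tiny_config)
        b = run_simulation(tiny_config)
        assert a.series.equals(b.series)
        assert np.array_equal(a.final_trust, b.final_trust)
        assert np.array_equal(a.final_snapshot.edges, b.final_snapshot.edges)

    def test_k_zero_is_the_no_communication_limit(self):
        cfg = SimConfig(n=50, k=0, rounds=400, seed=3, compute_forward=False)
        res = run_simulation(cfg)
        assert res.final_snapshot.m == 0
        # long-run group performance approaches the mean ability
        assert abs(res.series.iloc[-1]["rel_improvement"]) < 0.05

    def test_single_agent_run(self):
        cfg = SimConfig(n=1, rounds=80, seed=4, compute_forward=False)
        res = run_simulation(cfg)
        assert res.final_snapshot.m == 0
        assert abs(res.series.iloc[-1]["group_perf"] - res.abilities[0]) < 0.3

    def test_fast_environment_change_suppresses_hierarchy(self):
        """With p close to 1 yesterday's advice is worthless, so the
        communication network shows no more hierarchy than random graphs
        of the same size and density."""
        cfg = SimConfig(n=64, p=0.9, rounds=300, seed=6,
                        hierarchy_stride=10, compute_forward=False)
        res = run_simulation(cfg)
        hier = res.series.dropna(subset=["grc"])
        tail = hier[hier["round"] > 200]
        rng = np.random.default_rng(1)
        m = int(round(tail["avg_degree"].mean() * cfg.n))
        pairs = [(u, v) for u in range(cfg.n) for v in range(cfg.n) if u != v]
        er_grc = np.mean([
            global_reaching_centrality(
                (cfg.n, [pairs[i] for i in
                         rng.choice(len(pairs), m, replace=False)]))
            for _ in range(20)
        ])
        assert tail["grc"].mean() < er_grc + 0.1

    def test_invalid_config_raises_before_running(self):
        with pytest.raises(ConfigError):
            run_simulation(SimConfig(n=10, p=2.0))

    def test_trust_snapshots_collected(self, tiny_config):
        tiny_config.trust_snapshot_rounds = (10, 40)
        res = run_simulation(tiny_config)
        assert set(res.trust_snapshots) == {10, 40}
        assert res.trust_snapshots[10].shape == (16, 16)
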