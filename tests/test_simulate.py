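"""Synthetic population generator: mixtures, schedules, agent behavior."""

import numpy as np
import pytest

import trustmotives as tm
from trustmotives.simulate import largest_remainder_counts


class TestMixtureCounts:
    def test_reference_mixture(self):
        assert largest_remainder_counts([0.4, 0.1, 0.4, 0.1], 100) == [40, 10, 40, 10]

    def test_remainders_allocated_to_largest(self):
        assert largest_remainder_counts([0.5, 0.25, 0.25], 3) == [1, 1, 1]
        assert largest_remainder_counts([0.5, 0.25, 0.25], 5) == [3, 1, 1]

    def test_counts_sum_to_n(self):
        for n in (1, 7, 53, 100):
            counts = largest_remainder_counts([0.4, 0.1, 0.4, 0.1], n)
            assert sum(counts) == n


class TestSamplePopulation:
    def test_mixture_and_zone_membership(self, map236):
        spec = tm.PopulationSpec(20, seed=3)
        agents = tm.sample_population(spec, map236)
        by_strategy = {s: sum(a.strategy == s for a in agents)
                       for s in tm.STRATEGY_LABELS}
        assert by_strategy == {"IA": 8, "GA": 2, "MO": 8, "GR": 2}
        for agent in agents:
            assert tm.classify_participant(agent.theta, agent.phi, map236) \
                == agent.strategy

    def test_deterministic_given_seed(self, map236):
        spec = tm.PopulationSpec(10, seed=5)
        assert tm.sample_population(spec, map236) == tm.sample_population(spec, map236)

    def test_single_strategy_population(self, map236):
        spec = tm.PopulationSpec(1, {"IA": 1.0, "GA": 0, "MO": 0, "GR": 0}, seed=1)
        (agent,) = tm.sample_population(spec, map236)
        assert agent.strategy == "IA"

    def test_excessive_margin_empties_zone(self, map236):
        spec = tm.PopulationSpec(4, margin=50, seed=1)
        with pytest.raises(ValueError, match="empty after applying margin"):
            tm.sample_population(spec, map236)

    def test_intersection_of_maps_respects_both(self, map236, map468):
        spec = tm.PopulationSpec(40, seed=9)
        agents = tm.sample_population(spec, [map236, map468])
        for agent in agents:
            for m in (map236, map468):
                assert tm.classify_participant(agent.theta, agent.phi, m) \
                    == agent.strategy

    def test_invalid_proportions_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            tm.PopulationSpec(10, {"IA": 0.5, "GA": 0.2, "MO": 0.2, "GR": 0.2})


class TestSchedule:
    def test_exact_condition_counts(self, cfg236):
        schedule = tm.generate_investment_schedule(cfg236, seed=1)
        counts = {m: sum(t.true_multiplier == m for t in schedule) for m in (2, 4, 6)}
        assert counts == {2: 20, 4: 40, 6: 20}
        assert len(schedule) == 80

    def test_investment_support(self, cfg236):
        schedule = tm.generate_investment_schedule(cfg236, seed=2)
        assert all(1 <= t.investment <= 10 for t in schedule)

    def test_deterministic_given_seed(self, cfg236):
        a = tm.generate_investment_schedule(cfg236, seed=4)
        b = tm.generate_investment_schedule(cfg236, seed=4)
        assert a == b

    def test_shared_investments_across_blocks(self, cfg236, cfg468):
        investments = np.arange(80) % 10 + 1
        s1 = tm.generate_investment_schedule(cfg236, seed=1, investments=investments)
        s2 = tm.generate_investment_schedule(cfg468, seed=1, investments=investments)
        assert [t.investment for t in s1] == [t.investment for t in s2]


class TestSimulateAgent:
    def test_noise_free_matches_model_prediction(self, cfg236, schedule236):
        agent = tm.Agent("a", "MO", 0.10, 0.0, 0.0)
        rec = tm.simulate_agent(agent, schedule236, cfg236)
        preds = tm.predict_behavior_vector("MS", (0.10, 0.0), schedule236)
        assert np.array_equal(rec.returns, preds)

    def test_noise_free_greedy_agents_return_little_to_nothing(
        self, map236, cfg236, schedule236
    ):
        """Greedy-zone agents keep nearly everything (the residual moral
        weight at theta <= 0.5 still returns a few tokens on the richest
        trials), and return far less than inequity-averse agents."""
        totals = np.array([t.investment * t.true_multiplier for t in schedule236])

        def mean_fraction(zone):
            mixture = {s: float(s == zone) for s in tm.STRATEGY_LABELS}
            spec = tm.PopulationSpec(4, mixture, noise_sd=0.0, seed=8)
            fractions = []
            for agent in tm.sample_population(spec, map236):
                rec = tm.simulate_agent(agent, schedule236, cfg236)
                fractions.append(rec.returns.sum() / totals.sum())
            return np.mean(fractions)

        greedy = mean_fraction("GR")
        assert greedy <= 0.2
        assert greedy < mean_fraction("IA") / 2

    def test_guilt_averse_agent_invariant_across_conditions(self, cfg236):
        trials = [tm.TrialSpec(10, m2, 4, i) for i, m2 in enumerate((2, 4, 6))]
        agent = tm.Agent("a", "GA", 0.0, -0.09, 0.0)
        rec = tm.simulate_agent(agent, trials, cfg236)
        assert rec.returns.tolist() == [20, 20, 20]

    def test_noisy_returns_stay_feasible(self, cfg236, schedule236):
        agent = tm.Agent("a", "MO", 0.10, 0.0, 4.0)
        rec = tm.simulate_agent(agent, schedule236, cfg236, seed=3)
        totals = np.array([t.investment * t.true_multiplier for t in schedule236])
        assert (rec.returns >= 0).all() and (rec.returns <= totals).all()

    def test_noise_deterministic_given_seed(self, cfg236, schedule236):
        agent = tm.Agent("a", "MO", 0.10, 0.0, 1.0)
        r1 = tm.simulate_agent(agent, schedule236, cfg236, seed=3)
        r2 = tm.simulate_agent(agent, schedule236, cfg236, seed=3)
        assert np.array_equal(r1.returns, r2.returns)


class TestGenerateStudy:
    def test_two_block_shapes(self, cfg236, cfg468, map236, map468):
        spec = tm.PopulationSpec(10, noise_sd=1.0, seed=6)
        records, truth = tm.generate_study(
            spec, [cfg236, cfg468], seed=6, strategy_map=[map236, map468]
        )
        assert len(records) == 20
        assert len(truth) == 10
        assert {r.block_id for r in records} == {"block0", "block1"}
        by_block = {
            b: sorted(r.participant_id for r in records if r.block_id == b)
            for b in ("block0", "block1")
        }
        assert by_block["block0"] == by_block["block1"]

    def test_recovery_degrades_with_noise(self, cfg236, map236, schedule236):
        """Label recovery at noise 0 is at least as good as at noise 4."""
        rates = {}
        for noise in (0.0, 4.0):
            spec = tm.PopulationSpec(16, noise_sd=noise, seed=12)
            agents = tm.sample_population(spec, map236)
            hits = 0
            for i, agent in enumerate(agents):
                rec = tm.simulate_agent(agent, schedule236, cfg236, seed=100 + i)
                fit = tm.fit_model("MS", rec, n_restarts=60, seed=14)
                hits += (
                    tm.classify_participant(
                        fit.params["theta"], fit.params["phi"], map236
                    )
                    == agent.strategy
                )
            rates[noise] = hits / len(agents)
        assert rates[0.0] >= rates[4.0]
        assert rates[0.0] == 1.0
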