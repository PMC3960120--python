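"""Agent choice models and the three experiment simulators."""

from dataclasses import replace

import numpy as np
import pytest
from scipy import stats

from fetchstats import (
    AgentSpec,
    ChoiceContext,
    choice_distribution,
    design_for,
    simulate,
)
from fetchstats.agents import simulate_exp1, simulate_exp2, simulate_exp3
from fetchstats.trial_model import ValidationError, check_schedule, summarize_subject

EXP1_ROLES = ("target", "distracter", "distracter")
EXP3_ROLES = ("target", "distracter")


class TestChoiceDistribution:
    def test_random_is_uniform(self):
        probs = choice_distribution(AgentSpec(kind="random"),
                                    ChoiceContext(roles=EXP1_ROLES))
        assert np.allclose(probs, 1 / 3)

    def test_perfect_knower_is_deterministic(self):
        probs = choice_distribution(AgentSpec(kind="knower", theta=1.0),
                                    ChoiceContext(roles=EXP1_ROLES))
        assert np.allclose(probs, [1.0, 0.0, 0.0])

    def test_knower_spreads_remainder_uniformly(self):
        probs = choice_distribution(AgentSpec(kind="knower", theta=0.7),
                                    ChoiceContext(roles=EXP1_ROLES))
        assert np.allclose(probs, [0.7, 0.15, 0.15])

    def test_associative_follows_visible_object_when_target_occluded(self):
        context = ChoiceContext(roles=EXP3_ROLES, condition="target_occluded",
                                visible_role="distracter")
        probs = choice_distribution(AgentSpec(kind="associative", theta=0.9), context)
        assert probs[1] == pytest.approx(0.9)

    def test_associative_without_visible_object_falls_back_to_uniform(self):
        probs = choice_distribution(AgentSpec(kind="associative", theta=0.9),
                                    ChoiceContext(roles=EXP1_ROLES))
        assert np.allclose(probs, 1 / 3)

    def test_enhancement_weights_attended_slot(self):
        probs = choice_distribution(AgentSpec(kind="enhancement", w=2.0),
                                    ChoiceContext(roles=EXP1_ROLES, attended_slot=0))
        assert np.allclose(probs, [3 / 5, 1 / 5, 1 / 5])

    def test_learner_accuracy_ramps_monotonically(self):
        agent = AgentSpec(kind="learner", theta_start=0.4, theta_end=0.9, rate=0.5)
        accs = [agent.accuracy_at(t, 28) for t in range(1, 29)]
        assert all(a <= b + 1e-12 for a, b in zip(accs, accs[1:]))
        assert accs[0] < 0.5 < accs[-1]

    def test_distributions_are_normalized(self):
        for kind in ("random", "knower", "associative", "enhancement", "learner"):
            probs = choice_distribution(
                AgentSpec(kind=kind, theta=0.6, w=1.5),
                ChoiceContext(roles=EXP1_ROLES, visible_role="target",
                              attended_slot=1),
            )
            assert probs.min() >= 0 and probs.sum() == pytest.approx(1.0)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValidationError):
            AgentSpec(kind="telepath")


class TestSimulators:
    def test_exp1_random_agent_success_rates(self, exp1_design):
        firsts, overalls = [], []
        for seed in range(400):
            records = simulate_exp1(AgentSpec(kind="random"), exp1_design, seed)
            firsts.append(sum(r.first_attempt_success for r in records))
            overalls.append(sum(r.success for r in records))
        # first attempt succeeds w.p. 1/3; within two attempts w.p. 2/3
        assert np.mean(firsts) == pytest.approx(8.0, abs=0.35)
        assert np.mean(overalls) == pytest.approx(16.0, abs=0.35)

    def test_exp1_perfect_knower(self, exp1_design):
        records = simulate_exp1(AgentSpec(kind="knower", theta=1.0), exp1_design, 0)
        assert all(r.success_attempt == 1 for r in records)

    def test_exp2_random_agent_rates(self, exp2_design):
        corrects, labelled = [], []
        for seed in range(300):
            records = simulate_exp2(AgentSpec(kind="random"), exp2_design, seed)
            corrects.append(sum(r.success for r in records))
            labelled.append(sum(r.attempts[0] in ("target", "labelled_nontarget")
                                for r in records))
        assert np.mean(corrects) == pytest.approx(24 / 4, abs=0.35)
        assert np.mean(labelled) == pytest.approx(24 / 2, abs=0.4)

    def test_exp2_all_mass_on_labelled_objects(self, exp2_design):
        agent = AgentSpec(kind="weighted",
                          role_weights={"target": 1.0, "labelled_nontarget": 1.0})
        corrects = []
        for seed in range(200):
            records = simulate_exp2(agent, exp2_design, seed)
            assert all(r.attempts[0] != "distracter" for r in records)
            corrects.append(sum(r.success for r in records))
        assert np.mean(corrects) == pytest.approx(12.0, abs=0.5)

    def test_exp3_associative_condition_dissociation(self, exp3_design):
        records = simulate_exp3(AgentSpec(kind="associative", theta=1.0),
                                exp3_design, 123)
        s = summarize_subject(records, exp3_design)
        assert s.per_condition_correct.get("target_open", 0) == 14
        assert s.per_condition_correct.get("target_occluded", 0) == 0

    def test_exp3_perfect_knower_is_ceiling(self, exp3_design):
        records = simulate_exp3(AgentSpec(kind="knower", theta=1.0), exp3_design, 5)
        assert sum(r.success for r in records) == 28

    def test_exp3_learner_improves_over_windows(self, exp3_design):
        agent = AgentSpec(kind="learner", theta_start=0.5, theta_end=0.95, rate=0.5)
        first, last = [], []
        for seed in range(300):
            s = summarize_subject(simulate_exp3(agent, exp3_design, seed), exp3_design)
            first.append(s.first_window_correct)
            last.append(s.last_window_correct)
        assert np.mean(last) > np.mean(first) + 1.0

    def test_simulator_output_passes_validation_and_schedule_checks(self):
        for experiment in ("exp1", "exp2", "exp3"):
            design = design_for(experiment)
            records = simulate(experiment, AgentSpec(kind="random"), design, 77)
            assert len(records) == design.n_trials
            assert all(len(r.attempts) <= design.max_attempts for r in records)
            if experiment == "exp3":
                conditions = [r.condition for r in records]
                assert conditions.count("target_open") == 14

    def test_deterministic_per_seed(self, exp3_design):
        agent = AgentSpec(kind="knower", theta=0.6)
        assert simulate_exp3(agent, exp3_design, 9) == simulate_exp3(agent, exp3_design, 9)

    def test_design_experiment_mismatch_rejected(self, exp1_design):
        with pytest.raises(ValidationError):
            simulate_exp3(AgentSpec(kind="random"), exp1_design, 0)


class TestStatisticalSignatures:
    def test_moment_estimator_recovers_theta_at_moderate_n(self, exp1_design):
        design = replace(exp1_design, n_trials=240)
        for theta in (0.4, 0.8):
            hits = 0
            for seed in range(60):
                records = simulate_exp1(AgentSpec(kind="knower", theta=theta),
                                        design, seed)
                est = sum(r.first_attempt_success for r in records) / 240
                hits += abs(est - theta) <= 0.1
            assert hits >= 57  # ±0.1 covers >3 SEs at n=240

    def test_chance_knower_indistinguishable_from_random(self, exp1_design):
        # theta equal to the design's chance success rate: a two-sample test
        # on first-attempt counts should almost never reject
        rng = np.random.default_rng(314)
        significant = 0
        n_reps = 200
        for _ in range(n_reps):
            a = simulate_exp1(AgentSpec(kind="knower", theta=1 / 3), exp1_design,
                              int(rng.integers(2**31)))
            b = simulate_exp1(AgentSpec(kind="random"), exp1_design,
                              int(rng.integers(2**31)))
            ka = sum(r.first_attempt_success for r in a)
            kb = sum(r.first_attempt_success for r in b)
            table = [[ka, 24 - ka], [kb, 24 - kb]]
            significant += stats.fisher_exact(table)[1] <= 0.01
        assert significant / n_reps <= 0.02
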