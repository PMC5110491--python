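"""Agent model: background initialization, memory-based efficacy and
effort assessment, attempt decisions, model tracing, forward simulation."""

import numpy as np
import pandas as pd
import pytest

from efficacysim.agent import (AgentConfig, BackgroundConfig, BehaviorGoal,
                               assess_intended_effort, assess_self_efficacy,
                               decide_attempt, init_background, model_trace,
                               predict_success, simulate_forward)
from efficacysim.memory import (ExperienceChunk, MemoryParams, MemoryStore,
                                blend, retrieval_probabilities)
from efficacysim.rasch import rasch_probability
from efficacysim.study import DayPlan, GoalAssignment, StudySchedule, day_types


class TestInitBackground:
    def test_grid_size_is_product_of_levels(self, background_store):
        # 21 abilities x 5 difficulties x 2 efforts x 10 replicates
        assert len(background_store) == 2100

    def test_easy_cells_are_almost_all_successes(self):
        cfg = BackgroundConfig(ability_grid=[3.0], difficulty_grid=[-3.0],
                               effort_levels=[0.0], replicates=200, rng_seed=0)
        store = init_background(cfg)
        assert store.match({"outcome": "success"}).mean() > 0.95

    def test_fixed_seed_reproducibility(self):
        a = init_background(BackgroundConfig(rng_seed=7))
        b = init_background(BackgroundConfig(rng_seed=7))
        assert a.to_dict() == b.to_dict()

    def test_all_presentations_predate_day_one(self, background_store):
        assert all(c.presentation_times[-1] < 1.0
                   for c in background_store.chunks)

    def test_center_shifts_grids(self):
        store = init_background(BackgroundConfig(center=2.0, rng_seed=0))
        diffs = store.slot_values("difficulty")
        assert diffs.min() == pytest.approx(0.5)  # -1.5 + 2.0
        assert diffs.max() == pytest.approx(2.5)


class TestAssessments:
    GOAL = BehaviorGoal(behavior="x", difficulty=0.0, day=1)

    def test_constant_difficulty_successes_blend_to_that_value(self):
        store = MemoryStore()
        for t in (0.0, 0.2, 0.4):
            store.add_experience(ExperienceChunk(
                "x", 0.3, 0.0, 0.1, "success", [t]), merge_identical=False)
        cfg = AgentConfig()
        got = assess_self_efficacy(store, self.GOAL, 1.0, cfg,
                                   np.random.default_rng(0))
        assert got == pytest.approx(0.3)

    def test_recent_hard_successes_raise_efficacy(self):
        """Enactive mastery: adding recent high-difficulty successes to an
        otherwise identical store strictly raises blended self-efficacy."""
        def base_store():
            s = MemoryStore()
            for t in (0.0, 0.5):
                s.add_experience(ExperienceChunk(
                    "x", -0.8, 0.0, 0.1, "success", [t]),
                    merge_identical=False)
            return s
        cfg = AgentConfig()
        lo = assess_self_efficacy(base_store(), self.GOAL, 10.0, cfg,
                                  np.random.default_rng(1))
        enriched = base_store()
        enriched.add_experience(ExperienceChunk(
            "x", 0.9, 0.0, 0.1, "success", [9.0]), merge_identical=False)
        hi = assess_self_efficacy(enriched, self.GOAL, 10.0, cfg,
                                  np.random.default_rng(1))
        assert hi > lo

    def test_efficacy_floor_on_retrieval_failure(self):
        store = MemoryStore()
        store.add_experience(ExperienceChunk("x", 0.0, 0.0, 0.1, "failure",
                                             [0.0]))
        cfg = AgentConfig(efficacy_floor=-1.25)
        with pytest.warns(UserWarning):
            got = assess_self_efficacy(store, self.GOAL, 1.0, cfg,
                                       np.random.default_rng(0))
        assert got == -1.25

    def test_effort_constant_near_query_point(self):
        store = MemoryStore()
        for t in (0.0, 0.3):
            store.add_experience(ExperienceChunk(
                "x", 0.0, 0.0, 0.25, "success", [t]), merge_identical=False)
        cfg = AgentConfig()
        got = assess_intended_effort(store, 0.0, self.GOAL, 1.0, cfg,
                                     np.random.default_rng(2))
        assert got == pytest.approx(0.25)

    def test_harder_goals_recall_more_effort(self):
        """Successes that overcame large difficulty gaps carry high effort;
        a goal far above self-efficacy recalls them preferentially."""
        store = MemoryStore()
        # easy successes achieved with no effort
        for t in (0.0, 0.1, 0.2):
            store.add_experience(ExperienceChunk(
                "x", -1.0, -1.0, 0.0, "success", [t]), merge_identical=False)
        # hard-won successes far above ability, achieved with high effort
        for t in (0.3, 0.4, 0.5):
            store.add_experience(ExperienceChunk(
                "x", 1.5, -1.0, 1.0, "success", [t]), merge_identical=False)
        cfg = AgentConfig(memory=MemoryParams(noise_s=1e-6))
        theta = -1.0
        easy_goal = BehaviorGoal("x", -1.0, 1)
        hard_goal = BehaviorGoal("x", 1.5, 1)
        rng = np.random.default_rng(3)
        psi_easy = assess_intended_effort(store, theta, easy_goal, 1.0, cfg,
                                          rng)
        psi_hard = assess_intended_effort(store, theta, hard_goal, 1.0, cfg,
                                          rng)
        assert psi_hard > psi_easy

    def test_background_assessment_matches_composed_primitives(
            self, background_store):
        """Self-efficacy over the full background store equals an
        independent recomposition of activation -> softmax -> blend."""
        cfg = AgentConfig()
        now = 1.0
        got = assess_self_efficacy(background_store, self.GOAL, now, cfg,
                                   np.random.default_rng(11))
        mask = background_store.match({"outcome": "success"})
        base = background_store.base_level_activations(now)[mask]
        noise = np.random.default_rng(11).logistic(0, cfg.memory.noise_s,
                                                   base.size)
        probs = retrieval_probabilities(base + noise, cfg.memory.noise_s)
        expected = blend(background_store.slot_values("difficulty")[mask],
                         probs, cfg.memory.similarity_scale)
        assert got == pytest.approx(expected, abs=1e-12)


class TestPredictAndDecide:
    @pytest.mark.parametrize("theta, psi, delta, expected", [
        (0.0, 0.0, 0.0, 0.5),
        (0.5, 0.25, 0.0, 1 / (1 + np.exp(-0.75))),
    ])
    def test_logit_combination(self, theta, psi, delta, expected):
        assert predict_success(theta, psi, delta) == pytest.approx(expected)

    def test_zero_effort_reduces_to_rasch(self):
        for th, de in [(0.3, -0.4), (-1.0, 0.5)]:
            assert predict_success(th, 0.0, de) == pytest.approx(
                rasch_probability(th, de))

    def test_monotone_in_each_argument(self):
        assert predict_success(1.0, 0.0, 0.0) > predict_success(0.5, 0.0, 0.0)
        assert predict_success(0.0, 0.5, 0.0) > predict_success(0.0, 0.1, 0.0)
        assert predict_success(0.0, 0.0, 0.5) < predict_success(0.0, 0.0, 0.1)

    @pytest.mark.parametrize("p, thr, expected", [
        (0.6, 0.5, True),
        (0.5, 0.5, False),   # strict inequality at the threshold
        (0.01, 0.0, True),
        (1.0, 1.0, False),
    ])
    def test_attempt_is_strict_comparison(self, p, thr, expected):
        assert decide_attempt(p, thr) is expected


def _increasing_goals():
    return pd.DataFrame({
        "day": np.arange(1, 13),
        "exercise_id": [f"x{d}" for d in range(12)],
        "difficulty": np.linspace(0.6, 1.5, 12),
        "success": 1,
    })


class TestModelTrace:
    def test_empty_goal_list_gives_empty_trace(self, background_store):
        empty = pd.DataFrame(columns=["day", "exercise_id", "difficulty",
                                      "success"])
        tr = model_trace(empty, MemoryStore.from_dict(
            background_store.to_dict()), AgentConfig(),
            np.random.default_rng(0))
        assert len(tr) == 0

    def test_trace_contract(self, toy_log, background_store):
        sub = toy_log[toy_log.participant_id == "p1"].reset_index(drop=True)
        tr = model_trace(sub, MemoryStore.from_dict(background_store.to_dict()),
                         AgentConfig(), np.random.default_rng(0))
        assert len(tr) == len(sub)
        assert tr.predicted_p.between(0, 1, inclusive="neither").all()
        assert (tr.observed_success == sub.success).all()

    def test_theta_nondecreasing_under_mastery_in_noiseless_limit(self):
        """Daily successes at ever-harder goals (above the background range)
        produce a non-decreasing self-efficacy trajectory when noise -> 0."""
        cfg = AgentConfig(memory=MemoryParams(noise_s=1e-9))
        store = init_background(BackgroundConfig(rng_seed=1), cfg.memory)
        tr = model_trace(_increasing_goals(), store, cfg,
                         np.random.default_rng(0))
        assert np.all(np.diff(tr.theta.to_numpy()) >= -1e-9)

    def test_noiseless_trace_is_run_invariant(self):
        def run():
            cfg = AgentConfig(memory=MemoryParams(noise_s=1e-9))
            store = init_background(BackgroundConfig(rng_seed=1), cfg.memory)
            return model_trace(_increasing_goals(), store, cfg,
                               np.random.default_rng(123))
        pd.testing.assert_frame_equal(run(), run())

    def test_unsorted_goals_rejected(self, background_store):
        goals = _increasing_goals().iloc[::-1].reset_index(drop=True)
        with pytest.raises(ValueError):
            model_trace(goals, MemoryStore.from_dict(background_store.to_dict()),
                        AgentConfig(), np.random.default_rng(0))

    def test_missing_difficulty_rejected(self, background_store):
        goals = _increasing_goals().assign(difficulty=np.nan)
        with pytest.raises(ValueError):
            model_trace(goals, MemoryStore.from_dict(background_store.to_dict()),
                        AgentConfig(), np.random.default_rng(0))


def _flat_schedule(delta=-3.0):
    plans = []
    for d, t in zip(range(1, 29), day_types(28)):
        goals = ([GoalAssignment(f"e{j}", delta, 1) for j in range(3)]
                 if t == "exercise" else [])
        plans.append(DayPlan(day=d, day_type=t, goals=goals))
    return StudySchedule(condition="easy_fixed", days=plans)


class TestSimulateForward:
    def test_threshold_one_blocks_every_attempt(self):
        cfg = AgentConfig(attempt_threshold=1.0)
        store = init_background(BackgroundConfig(rng_seed=0), cfg.memory)
        sim = simulate_forward(_flat_schedule(), store, cfg,
                               np.random.default_rng(0))
        assert not sim.attempted.any()
        assert (sim.success == 0).all()

    def test_very_easy_schedule_is_mostly_achieved(self):
        """An able person on trivially easy goals adheres at >= 0.9."""
        rates = []
        for seed in range(3):
            store = init_background(BackgroundConfig(rng_seed=seed),
                                    AgentConfig().memory)
            sim = simulate_forward(_flat_schedule(-3.0), store, AgentConfig(),
                                   np.random.default_rng(seed),
                                   true_ability=0.0)
            rates.append(sim.success.mean())
        assert np.mean(rates) >= 0.9

    def test_fixed_seed_reproducibility(self):
        def run():
            cfg = AgentConfig()
            store = init_background(BackgroundConfig(rng_seed=3), cfg.memory)
            return simulate_forward(_flat_schedule(-1.0), store, cfg,
                                    np.random.default_rng(44))
        pd.testing.assert_frame_equal(run(), run())

    def test_record_per_goal_and_calendar(self):
        cfg = AgentConfig()
        store = init_background(BackgroundConfig(rng_seed=0), cfg.memory)
        sim = simulate_forward(_flat_schedule(), store, cfg,
                               np.random.default_rng(0))
        assert len(sim) == 12 * 3
        assert sorted(sim.day.unique()) == [1, 3, 5, 8, 10, 12, 15, 17, 19,
                                            22, 24, 26]
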