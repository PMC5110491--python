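"""Memory-based agent of self-efficacy and daily exercise adherence.

The agent faces one behavioral goal at a time.  It (1) blends the
difficulties of remembered successes into a self-efficacy assessment theta;
(2) blends the efforts of remembered successes at similar
self-efficacy/difficulty combinations into an intended effort psi;
(3) predicts its probability of success as the logistic of

    theta + psi - delta;

(4) attempts the goal when that probability clears a threshold; and
(5) stores the experience, which shapes every later assessment.  Because
assessment is a declarative-memory read-out, adherence inherits the
frequency, recency (lag), and blending (stress) signatures of base-level
learning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .memory import (SUCCESS, FAILURE, ExperienceChunk, MemoryParams,
                     MemoryStore, RetrievalFailure, blended_retrieve)

__all__ = [
    "BehaviorGoal",
    "EfficacyAssessment",
    "BackgroundConfig",
    "AgentConfig",
    "init_background",
    "assess_self_efficacy",
    "assess_intended_effort",
    "predict_success",
    "decide_attempt",
    "model_trace",
    "simulate_forward",
]

#: fraction of a day separating goal slots within one exercise day
SLOT_SPACING = 0.1


@dataclass
class BehaviorGoal:
    """One assigned goal: a behavior at some difficulty on some day."""

    behavior: str
    difficulty: float
    day: int
    slot_index: int = 1

    def __post_init__(self) -> None:
        if not np.isfinite(self.difficulty):
            raise ValueError("difficulty must be finite")
        if self.day < 1:
            raise ValueError("day must be >= 1")

    @property
    def time(self) -> float:
        """Event time in days (slots spaced within the day)."""
        return self.day + (self.slot_index - 1) * SLOT_SPACING


@dataclass
class EfficacyAssessment:
    """The agent's state for one goal: theta, psi, predicted s, attempt."""

    self_efficacy: float
    intended_effort: float
    predicted_success: float
    attempted: bool


@dataclass
class BackgroundConfig:
    """Grid of pre-program background experiences.

    Defaults follow the model-tracing initialization: abilities -1.0..+1.0
    in steps of 0.1, five difficulty levels -1.5..+0.5, efforts {0, 0.25},
    ten replicates per cell (2,100 chunks), with outcomes drawn Bernoulli
    with probability logistic(ability + effort - difficulty).

    ``center`` shifts both the ability and difficulty grids by a constant,
    which gives an agent a background of mastery experiences consistent
    with a pre-program self-efficacy level (the grids default to a
    population centered on zero).
    """

    ability_grid: Sequence[float] = field(
        default_factory=lambda: [round(a, 1) for a in np.arange(-1.0, 1.01, 0.1)])
    difficulty_grid: Sequence[float] = field(
        default_factory=lambda: [-1.5, -1.0, -0.5, 0.0, 0.5])
    effort_levels: Sequence[float] = field(default_factory=lambda: [0.0, 0.25])
    replicates: int = 10
    rng_seed: int = 0
    history_span: float = 30.0  # days before day 1 over which chunks are spread
    center: float = 0.0

    def __post_init__(self) -> None:
        if (not len(self.ability_grid) or not len(self.difficulty_grid)
                or not len(self.effort_levels)):
            raise ValueError("grids must be non-empty")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


@dataclass
class AgentConfig:
    """Agent-level knobs on top of the memory parameters.

    attempt_threshold
        Goals with predicted success strictly above this are attempted.
    mismatch_weight
        Weight of the similarity penalty used when recalling intended
        effort at the current (theta, delta) combination.
    efficacy_floor
        Self-efficacy reported when no success can be recalled at all.
    """

    memory: MemoryParams = field(default_factory=MemoryParams)
    attempt_threshold: float = 0.25
    mismatch_weight: float = 1.0
    efficacy_floor: float = -1.0


def init_background(config: BackgroundConfig,
                    memory_params: MemoryParams | None = None,
                    start_day: float = 1.0) -> MemoryStore:
    """Populate a memory store with the pre-program experience grid.

    Presentation times are spread uniformly over the ``history_span`` days
    preceding ``start_day`` so background chunks carry moderate, roughly
    equal activations at program start.
    """
    rng = np.random.default_rng(config.rng_seed)
    store = MemoryStore(memory_params or MemoryParams())
    c0 = config.center
    cells = [(a + c0, d + c0, e) for a in config.ability_grid
             for d in config.difficulty_grid
             for e in config.effort_levels
             for _ in range(config.replicates)]
    times = np.sort(rng.uniform(start_day - config.history_span,
                                start_day - 0.5, size=len(cells)))
    p = expit(np.array([a + e - d for a, d, e in cells]))
    success = rng.random(len(cells)) < p
    for (a, d, e), t, s in zip(cells, times, success):
        store.add_experience(ExperienceChunk(
            behavior="background", difficulty=d, ability=a, effort=e,
            outcome=SUCCESS if s else FAILURE, presentation_times=[float(t)]),
            merge_identical=False)
    return store


def assess_self_efficacy(memory: MemoryStore, goal: BehaviorGoal, now: float,
                         config: AgentConfig,
                         rng: np.random.Generator) -> float:
    """Blend the difficulties of remembered successes into theta.

    Self-efficacy is what the agent remembers having overcome: a blended
    retrieval over success chunks of the DIFFICULTY slot.  Falls back to
    ``config.efficacy_floor`` (with a warning) if no success is retrievable.
    """
    try:
        return blended_retrieve(memory, {"outcome": SUCCESS}, "difficulty",
                                now, config.memory, rng)
    except RetrievalFailure:
        warnings.warn("no retrievable success; self-efficacy floored",
                      UserWarning, stacklevel=2)
        return config.efficacy_floor


def assess_intended_effort(memory: MemoryStore, self_efficacy: float,
                           goal: BehaviorGoal, now: float,
                           config: AgentConfig,
                           rng: np.random.Generator) -> float:
    """Blend the efforts of successes at similar (theta, delta) into psi.

    Each success chunk's activation is penalized by its dissimilarity to
    the current self-efficacy and goal difficulty,

        penalty = w * (|ability_i - theta| + |difficulty_i - delta|) / range,

    so the efforts recalled are those that earned success in comparable
    situations.  The result is floored at 0.
    """
    mp = config.memory
    penalty = config.mismatch_weight * (
        np.abs(memory.slot_values("ability") - self_efficacy)
        + np.abs(memory.slot_values("difficulty") - goal.difficulty)
    ) / mp.similarity_scale
    try:
        psi = blended_retrieve(memory, {"outcome": SUCCESS}, "effort", now,
                               mp, rng, activation_penalty=penalty)
    except RetrievalFailure:
        warnings.warn("no retrievable success; intended effort set to 0",
                      UserWarning, stacklevel=2)
        return 0.0
    return max(psi, 0.0)


def predict_success(self_efficacy: float, intended_effort: float,
                    difficulty: float) -> float:
    """logit(s) = theta + psi - delta; with psi = 0 this is the Rasch model."""
    for v in (self_efficacy, intended_effort, difficulty):
        if not np.isfinite(v):
            raise ValueError("inputs must be finite")
    return float(expit(self_efficacy + intended_effort - difficulty))


def decide_attempt(predicted_success: float, threshold: float) -> bool:
    """Attempt iff predicted success strictly exceeds the threshold."""
    if not 0 <= predicted_success <= 1 or not 0 <= threshold <= 1:
        raise ValueError("probabilities must be in [0, 1]")
    return predicted_success > threshold


def _assess_goal(memory: MemoryStore, goal: BehaviorGoal,
                 config: AgentConfig,
                 rng: np.random.Generator) -> EfficacyAssessment:
    now = goal.time
    theta = assess_self_efficacy(memory, goal, now, config, rng)
    psi = assess_intended_effort(memory, theta, goal, now, config, rng)
    s = predict_success(theta, psi, goal.difficulty)
    return EfficacyAssessment(self_efficacy=theta, intended_effort=psi,
                              predicted_success=s,
                              attempted=decide_attempt(
                                  s, config.attempt_threshold))


def _store_experience(memory: MemoryStore, goal: BehaviorGoal,
                      assessment: EfficacyAssessment, success: bool) -> None:
    """Record the episode, attributing success beyond one's efficacy to effort.

    A success at a goal harder than the current self-efficacy is remembered
    as having required effort at least equal to the gap overcome, so that
    later recall of intended effort is higher for experiences in which the
    difficulties overcome were well beyond the self-efficacy of the time.
    Failures store the effort that was intended (it did not suffice).
    """
    if success:
        effort = max(assessment.intended_effort,
                     goal.difficulty - assessment.self_efficacy, 0.0)
    else:
        effort = assessment.intended_effort
    memory.add_experience(ExperienceChunk(
        behavior=goal.behavior, difficulty=goal.difficulty,
        ability=assessment.self_efficacy, effort=effort,
        outcome=SUCCESS if success else FAILURE,
        presentation_times=[goal.time]), merge_identical=False)


def model_trace(participant_goals: pd.DataFrame, background: MemoryStore,
                config: AgentConfig,
                rng: np.random.Generator) -> pd.DataFrame:
    """Trace the agent through one participant's recorded goal sequence.

    ``participant_goals`` must be sorted by day then slot and carry columns
    ``day``, ``exercise_id``, ``difficulty``, ``success``.  For every goal
    the agent assesses theta and psi, predicts success, and then stores the
    *observed* outcome — the observed experience enters memory whether or
    not the agent itself would have attempted.  ``background`` is consumed
    (mutated); pass a fresh store per participant.
    """
    df = participant_goals
    if "slot_index" not in df.columns:
        df = df.assign(slot_index=df.groupby("day").cumcount() + 1)
    order = df[["day", "slot_index"]].to_numpy()
    if np.any(np.diff(order[:, 0] + order[:, 1] * SLOT_SPACING * 0.5) < 0):
        raise ValueError("participant goals must be sorted by day then slot")
    if "difficulty" not in df.columns or df["difficulty"].isna().any():
        raise ValueError("every goal needs a difficulty (from the Rasch fit)")
    rows = []
    for rec in df.itertuples(index=False):
        goal = BehaviorGoal(behavior=str(rec.exercise_id),
                            difficulty=float(rec.difficulty),
                            day=int(rec.day), slot_index=int(rec.slot_index))
        a = _assess_goal(background, goal, config, rng)
        observed = bool(rec.success)
        _store_experience(background, goal, a, observed)
        rows.append({"day": goal.day, "slot_index": goal.slot_index,
                     "exercise_id": goal.behavior,
                     "difficulty": goal.difficulty,
                     "theta": a.self_efficacy, "psi": a.intended_effort,
                     "predicted_p": a.predicted_success,
                     "attempted": a.attempted,
                     "predicted_success": int(a.predicted_success > 0.5),
                     "observed_success": int(observed)})
    return pd.DataFrame(rows)


def simulate_forward(goal_provider, background: MemoryStore,
                     config: AgentConfig,
                     rng: np.random.Generator,
                     true_ability: float | None = None,
                     day_effect_sd: float = 0.0,
                     day_effect_ar: float = 0.0) -> pd.DataFrame:
    """Run the agent freely over a goal schedule, sampling outcomes.

    ``goal_provider`` is either a :class:`~efficacysim.study.StudySchedule`
    or any object with ``next_goals(day, feedback)`` yielding the day's
    goals given the previous exercise day's success count (the adaptive
    coaching loop).  Attempted goals get sampled outcomes and are stored in
    memory; unattempted goals are recorded as failures and store nothing.

    By default an attempted goal succeeds with the agent's own predicted
    probability.  When ``true_ability`` is given, outcomes are instead
    drawn from the world model that also generates background experiences —
    Bernoulli(logistic(true_ability + psi - delta + u_day)) — so that
    perceived self-efficacy (which drives attempt and effort) and actual
    capability (which drives the outcome) can disagree.  ``u_day`` is a
    stationary day-level engagement disturbance with sd ``day_effect_sd``,
    shared by the day's goals and carried across exercise days as an AR(1)
    process with coefficient ``day_effect_ar``: daily adherence rises and
    falls with the day (time, fatigue, motivation) and those fluctuations
    persist over stretches of days.
    """
    provider = (_FixedProvider(goal_provider)
                if hasattr(goal_provider, "days") else goal_provider)
    rows = []
    feedback: int | None = None
    u_day = 0.0
    first_u = True
    for day in provider.day_range():
        goals = provider.next_goals(day, feedback)
        if goals is None:
            continue
        if day_effect_sd > 0:
            if first_u:
                u_day = rng.normal(0.0, day_effect_sd)
                first_u = False
            else:
                phi = day_effect_ar
                u_day = (phi * u_day
                         + np.sqrt(1.0 - phi ** 2) * rng.normal(0.0, day_effect_sd))
        day_success = []
        for goal in goals:
            a = _assess_goal(background, goal, config, rng)
            if a.attempted:
                p_world = (a.predicted_success if true_ability is None
                           else float(expit(true_ability + a.intended_effort
                                            - goal.difficulty + u_day)))
                success = bool(rng.random() < p_world)
                _store_experience(background, goal, a, success)
            else:
                success = False
            day_success.append(success)
            rows.append({"day": goal.day, "slot_index": goal.slot_index,
                         "exercise_id": goal.behavior,
                         "difficulty": goal.difficulty,
                         "theta": a.self_efficacy, "psi": a.intended_effort,
                         "predicted_p": a.predicted_success,
                         "attempted": a.attempted,
                         "success": int(success)})
        feedback = sum(day_success)
    return pd.DataFrame(rows)


class _FixedProvider:
    """Adapts a fixed StudySchedule to the goal-provider interface."""

    def __init__(self, schedule) -> None:
        self.schedule = schedule

    def day_range(self):
        return range(1, len(self.schedule.days) + 1)

    def next_goals(self, day, feedback):
        plan = self.schedule.days[day - 1]
        if plan.day_type != "exercise":
            return None
        return [BehaviorGoal(behavior=g.exercise_id, difficulty=g.difficulty,
                             day=day, slot_index=i + 1)
                for i, g in enumerate(plan.goals)]
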