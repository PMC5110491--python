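"""Synthetic 28-day adaptive exercise-program generator.

Emulates the design of the three-arm mHealth trial the models target:
~60+ adults split across an *adaptive* arm (goal level moves with the
previous exercise day's performance), an *easy-fixed* arm (slow common
ramp), and a *difficult-fixed* arm (steeper common ramp), each running
28 days with exercise days on Mon/Wed/Fri (three goals per exercise day),
meditation days Tue/Thu/Sat, and rest on Sundays.  Person abilities are
approximately normal around zero and the 46-exercise difficulty pool is
slightly left-skewed (median near -0.21 logits), both on the Rasch logit
scale.  Datasets can be synthesized from three ground truths — a static
Rasch process, the memory-based agent, or the closed-form impulse model —
with a sidecar of every true parameter for recovery testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import skewnorm

from .agent import AgentConfig, BackgroundConfig, BehaviorGoal, init_background, simulate_forward
from .impulse import GoalHistory, ImpulseParams, self_efficacy_gain

__all__ = [
    "CONDITIONS",
    "ExercisePool",
    "GoalAssignment",
    "DayPlan",
    "StudySchedule",
    "day_types",
    "generate_population",
    "generate_exercise_pool",
    "build_schedule",
    "fixed_ramp_levels",
    "adaptive_level_sequence",
    "AdaptiveGoalProvider",
    "synthesize_study",
]

CONDITIONS = ("adaptive", "easy_fixed", "difficult_fixed")

N_DAYS = 28
GOALS_PER_DAY = 3

# Surrogate level ramps (level index per exercise day, linear, clipped to
# the pool's levels).  The original programs' level-by-day tables are not
# public; these are design values chosen so the fixed ramps straddle the
# adaptive arm's typical trajectory and sit in the mid-range of the pool,
# where goals lie above baseline self-efficacy and mastery can build.
EASY_START, EASY_END = 1, 3
DIFFICULT_START, DIFFICULT_END = 4, 9
ADAPTIVE_START = 3
DEFAULT_N_LEVELS = 14


def day_types(n_days: int = N_DAYS) -> list[str]:
    """Day-type tags for a program starting on a Monday.

    Exercise Mon/Wed/Fri, meditation Tue/Thu/Sat, rest Sunday.
    """
    pattern = ["exercise", "meditation", "exercise", "meditation",
               "exercise", "meditation", "rest"]
    return [pattern[(d - 1) % 7] for d in range(1, n_days + 1)]


@dataclass
class GoalAssignment:
    exercise_id: str
    difficulty: float
    level: int


@dataclass
class DayPlan:
    day: int
    day_type: str
    goals: list[GoalAssignment] = field(default_factory=list)


@dataclass
class StudySchedule:
    """Per-day goal assignments for one participant's 28-day program."""

    condition: str
    days: list[DayPlan]

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")
        expected = day_types(len(self.days))
        for plan, exp in zip(self.days, expected):
            if plan.day_type != exp:
                raise ValueError(
                    f"day {plan.day}: type {plan.day_type!r} violates the "
                    f"weekly pattern (expected {exp!r})")
            if plan.day_type == "exercise" and len(plan.goals) != GOALS_PER_DAY:
                raise ValueError(
                    f"day {plan.day}: exercise days carry exactly "
                    f"{GOALS_PER_DAY} goals")

    @property
    def exercise_days(self) -> list[int]:
        return [p.day for p in self.days if p.day_type == "exercise"]


class ExercisePool:
    """A pool of exercises with true difficulties, binned into levels.

    Levels are contiguous slices of the difficulty-sorted pool, so level
    medians increase monotonically with level index.
    """

    def __init__(self, table: pd.DataFrame, n_levels: int) -> None:
        self.table = table.sort_values("difficulty").reset_index(drop=True)
        self.n_levels = n_levels
        chunks = np.array_split(np.arange(len(self.table)), n_levels)
        lev = np.empty(len(self.table), dtype=int)
        for i, c in enumerate(chunks):
            lev[c] = i + 1
        self.table["level"] = lev

    def __len__(self) -> int:
        return len(self.table)

    @property
    def difficulties(self) -> dict[str, float]:
        return dict(zip(self.table["exercise_id"], self.table["difficulty"]))

    def level_members(self, level: int) -> pd.DataFrame:
        if not 1 <= level <= self.n_levels:
            raise ValueError(f"level {level} outside 1..{self.n_levels}")
        return self.table[self.table["level"] == level]

    def sample_goals(self, level: int, n: int,
                     rng: np.random.Generator) -> list[GoalAssignment]:
        m = self.level_members(level)
        idx = rng.choice(len(m), size=n, replace=len(m) < n)
        return [GoalAssignment(exercise_id=m.iloc[i]["exercise_id"],
                               difficulty=float(m.iloc[i]["difficulty"]),
                               level=level) for i in idx]

    def level_medians(self) -> np.ndarray:
        return (self.table.groupby("level")["difficulty"].median()
                .to_numpy())


def generate_population(n: int, ability_sd: float = 0.5,
                        rng: np.random.Generator | int | None = None
                        ) -> np.ndarray:
    """Draw ``n`` person abilities from Normal(0, ability_sd^2)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(rng)
    return rng.normal(0.0, ability_sd, size=n)


def generate_exercise_pool(n_exercises: int = 46, skew: float = -4.0,
                           target_median: float = -0.21,
                           spread_sd: float = 0.6,
                           n_levels: int = DEFAULT_N_LEVELS,
                           rng: np.random.Generator | int | None = None
                           ) -> ExercisePool:
    """Skew-normal difficulty pool with median near ``target_median``.

    Negative ``skew`` puts the long tail below zero (most exercises easy,
    a few hard), matching the left-shifted empirical distribution;
    ``skew=0`` yields a symmetric pool.
    """
    if n_exercises < 5:
        raise ValueError("n_exercises must be >= 5")
    rng = np.random.default_rng(rng)
    raw = skewnorm.rvs(skew, size=n_exercises, random_state=rng)
    raw = raw - skewnorm.median(skew)
    sd = raw.std()
    if sd > 0:
        raw = raw / sd * spread_sd
    diffs = raw + target_median
    table = pd.DataFrame({
        "exercise_id": [f"ex{i + 1:02d}" for i in range(n_exercises)],
        "difficulty": diffs,
    })
    return ExercisePool(table, n_levels=n_levels)


def _ramp_levels(start: int, end: int, n_steps: int, n_levels: int
                 ) -> list[int]:
    lev = np.rint(np.linspace(start, end, n_steps)).astype(int)
    return list(np.clip(lev, 1, n_levels))


def fixed_ramp_levels(condition: str, n_exercise_days: int,
                      n_levels: int = DEFAULT_N_LEVELS) -> list[int]:
    """Level index per exercise day for the fixed-schedule arms."""
    if condition == "easy_fixed":
        return _ramp_levels(EASY_START, EASY_END, n_exercise_days, n_levels)
    if condition == "difficult_fixed":
        return _ramp_levels(DIFFICULT_START, DIFFICULT_END, n_exercise_days,
                            n_levels)
    raise ValueError(f"no fixed ramp for condition {condition!r}")


def _level_step(feedback, n_goals: int = GOALS_PER_DAY) -> int:
    """Coaching-rule move from one exercise day's performance.

    Advance one level after an all-success day, regress one level after a
    day with no success, hold the level otherwise.  ``feedback`` is either
    the count of achieved goals or a bool (True = all achieved, False =
    none achieved).
    """
    if isinstance(feedback, (bool, np.bool_)):
        return 1 if feedback else -1
    k = int(feedback)
    if not 0 <= k <= n_goals:
        raise ValueError(f"feedback count {k} outside 0..{n_goals}")
    if k == n_goals:
        return 1
    if k == 0:
        return -1
    return 0


def adaptive_level_sequence(feedback: Sequence, n_levels: int,
                            start: int = ADAPTIVE_START) -> list[int]:
    """Level per exercise day under the coaching rule.

    ``feedback[i]`` is exercise day i's performance (see
    :func:`_level_step`); levels are clipped to [1, n_levels].
    """
    levels = [start]
    for fb in feedback[:-1]:
        nxt = levels[-1] + _level_step(fb)
        levels.append(int(np.clip(nxt, 1, n_levels)))
    return levels


def build_schedule(condition: str, pool: ExercisePool,
                   performance_feedback: Sequence[bool] | None = None,
                   n_days: int = N_DAYS,
                   rng: np.random.Generator | int | None = None
                   ) -> StudySchedule:
    """Assemble a participant's 28-day schedule for one condition.

    The adaptive condition requires ``performance_feedback`` — per exercise
    day, whether all goals were achieved — because its levels depend on it.
    """
    rng = np.random.default_rng(rng)
    types = day_types(n_days)
    ex_days = [d for d, t in zip(range(1, n_days + 1), types)
               if t == "exercise"]
    if condition == "adaptive":
        if performance_feedback is None:
            raise ValueError("adaptive schedules require performance_feedback")
        if len(performance_feedback) < len(ex_days):
            raise ValueError(
                f"feedback for {len(ex_days)} exercise days required")
        levels = adaptive_level_sequence(list(performance_feedback)[:len(ex_days)],
                                         pool.n_levels)
    else:
        levels = fixed_ramp_levels(condition, len(ex_days), pool.n_levels)
    lev_by_day = dict(zip(ex_days, levels))
    plans = []
    for d, t in zip(range(1, n_days + 1), types):
        goals = (pool.sample_goals(lev_by_day[d], GOALS_PER_DAY, rng)
                 if t == "exercise" else [])
        plans.append(DayPlan(day=d, day_type=t, goals=goals))
    return StudySchedule(condition=condition, days=plans)


class AdaptiveGoalProvider:
    """Feeds the agent adaptive goals day by day, reacting to its outcomes."""

    def __init__(self, pool: ExercisePool, rng: np.random.Generator,
                 n_days: int = N_DAYS, start_level: int = ADAPTIVE_START
                 ) -> None:
        self.pool = pool
        self.rng = rng
        self.n_days = n_days
        self.level = start_level
        self.types = day_types(n_days)
        self._seen_first = False

    def day_range(self):
        return range(1, self.n_days + 1)

    def next_goals(self, day: int, feedback: bool | None):
        if self.types[day - 1] != "exercise":
            return None
        if self._seen_first:
            if feedback is None:
                raise ValueError("adaptive provider needs day feedback")
            self.level = int(np.clip(self.level + _level_step(feedback),
                                     1, self.pool.n_levels))
        self._seen_first = True
        return [BehaviorGoal(behavior=g.exercise_id, difficulty=g.difficulty,
                             day=day, slot_index=i + 1)
                for i, g in enumerate(
                    self.pool.sample_goals(self.level, GOALS_PER_DAY,
                                           self.rng))]


# ---------------------------------------------------------------------------
# end-to-end synthesis

_SCHEMA = ["participant_id", "day", "exercise_id", "success", "condition",
           "difficulty"]


def _impulse_participant(theta: float, condition: str, pool: ExercisePool,
                         params: ImpulseParams, rng: np.random.Generator,
                         n_days: int = N_DAYS) -> list[dict]:
    """Sequentially simulate one participant from the impulse model."""
    types = day_types(n_days)
    ex_days = [d for d, t in zip(range(1, n_days + 1), types)
               if t == "exercise"]
    fixed = (fixed_ramp_levels(condition, len(ex_days), pool.n_levels)
             if condition != "adaptive" else None)
    level = ADAPTIVE_START
    hist = GoalHistory(np.full(n_days, np.nan), np.zeros(n_days, dtype=bool))
    rows = []
    for i, d in enumerate(ex_days):
        lev = fixed[i] if fixed is not None else level
        goals = pool.sample_goals(lev, GOALS_PER_DAY, rng)
        dbar = float(np.mean([g.difficulty for g in goals]))
        hist.mean_difficulty[d - 1] = dbar
        # sigma(t) and the alpha-term are shared by the day's goals
        sig = self_efficacy_gain(hist, d, params)
        outcomes = []
        for g in goals:
            eta = (params.beta0 + theta - g.difficulty
                   + params.alpha * d ** -params.decay_d + sig)
            s = bool(rng.random() < expit(eta))
            outcomes.append(s)
            rows.append({"participant_id": None, "day": d,
                         "exercise_id": g.exercise_id, "success": int(s),
                         "condition": condition,
                         "difficulty": g.difficulty})
        hist.success[d - 1] = any(outcomes)
        if fixed is None:
            level = int(np.clip(level + _level_step(sum(outcomes)),
                                1, pool.n_levels))
    return rows


def synthesize_study(n_per_condition: int = 20,
                     ground_truth: str = "rasch-static",
                     params: dict | None = None,
                     seed: int = 0) -> tuple[pd.DataFrame, dict]:
    """Generate a full synthetic adherence log plus a truth sidecar.

    Ground truths:

    ``"rasch-static"``
        Success ~ Bernoulli(logistic(theta_i - delta_j)) with no dynamics.
        Exercises are assigned uniformly at random from the whole pool (a
        linking design that keeps every exercise observed across abilities,
        which level-ramped assignment cannot), on the standard exercise-day
        calendar.
    ``"agent"``
        The memory-based agent run forward under its condition's schedule
        (adaptive goals react to the agent's own outcomes).
    ``"impulse"``
        The closed-form impulse model run sequentially day by day.

    Returns ``(records, truth)`` where ``truth`` holds every generating
    parameter (abilities, difficulties, model params, seed).
    """
    if ground_truth not in ("rasch-static", "agent", "impulse"):
        raise ValueError(f"unknown ground truth {ground_truth!r}")
    params = dict(params or {})
    rng = np.random.default_rng(seed)
    pool = generate_exercise_pool(
        n_exercises=params.get("n_exercises", 46),
        spread_sd=params.get("pool_spread_sd", 0.6),
        rng=rng)
    n_total = n_per_condition * len(CONDITIONS)
    abilities = generate_population(n_total,
                                    ability_sd=params.get("ability_sd", 0.5),
                                    rng=rng)
    n_days = params.get("n_days", N_DAYS)
    types = day_types(n_days)
    ex_days = [d for d, t in zip(range(1, n_days + 1), types)
               if t == "exercise"]

    rows: list[dict] = []
    truth: dict = {"ground_truth": ground_truth, "seed": seed,
                   "difficulties": pool.difficulties,
                   "n_per_condition": n_per_condition,
                   "conditions": list(CONDITIONS)}
    pid = 0
    pid_ability = {}
    for condition in CONDITIONS:
        for _ in range(n_per_condition):
            pid_str = f"p{pid + 1:03d}"
            theta = float(abilities[pid])
            pid_ability[pid_str] = theta
            if ground_truth == "rasch-static":
                for d in ex_days:
                    idx = rng.integers(0, len(pool), size=GOALS_PER_DAY)
                    for i in idx:
                        row = pool.table.iloc[int(i)]
                        p = expit(theta - row["difficulty"])
                        rows.append({
                            "participant_id": pid_str, "day": d,
                            "exercise_id": row["exercise_id"],
                            "success": int(rng.random() < p),
                            "condition": condition,
                            "difficulty": float(row["difficulty"])})
            elif ground_truth == "agent":
                # background mastery history consistent with the person's
                # pre-program ability: both grids centered on theta
                bg_cfg = BackgroundConfig(
                    rng_seed=int(rng.integers(0, 2 ** 31)), center=theta)
                agent_cfg = params.get("agent_config") or AgentConfig()
                store = init_background(bg_cfg, agent_cfg.memory)
                day_sd = params.get("day_effect_sd", 1.5)
                day_ar = params.get("day_effect_ar", 0.7)
                if condition == "adaptive":
                    provider = AdaptiveGoalProvider(pool, rng, n_days=n_days)
                    sim = simulate_forward(provider, store, agent_cfg, rng,
                                           true_ability=theta,
                                           day_effect_sd=day_sd,
                                           day_effect_ar=day_ar)
                else:
                    sched = build_schedule(condition, pool, rng=rng,
                                           n_days=n_days)
                    sim = simulate_forward(sched, store, agent_cfg, rng,
                                           true_ability=theta,
                                           day_effect_sd=day_sd,
                                           day_effect_ar=day_ar)
                for rec in sim.itertuples(index=False):
                    rows.append({"participant_id": pid_str, "day": int(rec.day),
                                 "exercise_id": rec.exercise_id,
                                 "success": int(rec.success),
                                 "condition": condition,
                                 "difficulty": float(rec.difficulty)})
            else:  # impulse
                ip = params.get("impulse_params") or ImpulseParams(
                    beta0=0.12, beta1=-0.18, gamma=0.23, decay_d=0.94,
                    alpha=0.0)
                for r in _impulse_participant(theta, condition, pool, ip,
                                              rng, n_days=n_days):
                    r["participant_id"] = pid_str
                    rows.append(r)
            pid += 1
    truth["abilities"] = pid_ability
    if ground_truth == "impulse":
        ip = params.get("impulse_params") or ImpulseParams(
            beta0=0.12, beta1=-0.18, gamma=0.23, decay_d=0.94, alpha=0.0)
        truth["impulse_params"] = {"beta0": ip.beta0, "beta1": ip.beta1,
                                   "gamma": ip.gamma, "d": ip.decay_d,
                                   "alpha": ip.alpha}
    records = pd.DataFrame(rows, columns=_SCHEMA)
    return records, truth
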