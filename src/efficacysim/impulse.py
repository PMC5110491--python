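"""Closed-form impulse model of self-efficacy gain and daily adherence.

Each day on which a participant achieves at least one assigned goal emits a
self-efficacy impulse whose size grows with the day's *stress* increment —
the rise of that day's mean assigned difficulty over the mean difficulty of
the last previously successful day:

    Delta_k = dbar_k - dbar_m.

Impulses decay as a power function of lag and accumulate into the gain

    sigma(t) = sum_{k<t, day k successful} (t - k)^(-d) * (beta1 + gamma * Delta_k),

and the probability that person i succeeds at goal j on day t is the
logistic of

    beta0 + theta_i - delta_j + alpha * t^(-d) + sigma(t),

where theta and delta come from the Rasch measurement model and the
alpha-term is a decaying pre-program impulse of intention to change.
Fitting minimizes squared residuals between observed and predicted success
rates pooled by condition and day (nonlinear least squares with bounds),
with a per-trial Bernoulli likelihood available as an alternative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import least_squares, minimize
from scipy.special import expit

from .rasch import RaschFit

__all__ = [
    "ImpulseParams",
    "GoalHistory",
    "stress_increment",
    "self_efficacy_gain",
    "success_probability",
    "build_histories",
    "fit_impulse",
    "ImpulseFitReport",
]


@dataclass
class ImpulseParams:
    """Parameters (beta0, beta1, gamma, d, alpha) of the impulse model."""

    beta0: float = 0.0
    beta1: float = 0.0
    gamma: float = 0.0
    decay_d: float = 0.5
    alpha: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.decay_d <= 1.0:
            raise ValueError(f"decay_d must be in (0, 1], got {self.decay_d}")

    def as_array(self) -> np.ndarray:
        return np.array([self.beta0, self.beta1, self.gamma, self.decay_d,
                         self.alpha])

    @classmethod
    def from_array(cls, x) -> "ImpulseParams":
        return cls(beta0=float(x[0]), beta1=float(x[1]), gamma=float(x[2]),
                   decay_d=float(x[3]), alpha=float(x[4]))


@dataclass
class GoalHistory:
    """One participant's day-indexed goal record over a program.

    ``mean_difficulty[k-1]`` is the mean assigned difficulty on day k (NaN on
    days without goals); ``success[k-1]`` is True when at least one goal was
    achieved that day.
    """

    mean_difficulty: np.ndarray
    success: np.ndarray

    def __post_init__(self) -> None:
        self.mean_difficulty = np.asarray(self.mean_difficulty, dtype=float)
        self.success = np.asarray(self.success, dtype=bool)
        if self.mean_difficulty.shape != self.success.shape:
            raise ValueError("mean_difficulty and success must align")
        if np.any(self.success & ~np.isfinite(self.mean_difficulty)):
            raise ValueError("successful day without a mean difficulty")

    @property
    def n_days(self) -> int:
        return len(self.success)

    def stress(self) -> np.ndarray:
        """Delta_k for every day (0 where undefined or goal-free)."""
        out = np.zeros(self.n_days)
        last = np.nan
        for k in range(self.n_days):
            if np.isfinite(self.mean_difficulty[k]) and np.isfinite(last):
                out[k] = self.mean_difficulty[k] - last
            if self.success[k]:
                last = self.mean_difficulty[k]
        return out


def stress_increment(history: GoalHistory, day: int) -> float:
    """Stress Delta_k of day ``day`` (1-based): dbar_k minus the mean
    difficulty of the last successful day before it; 0 when no prior
    successful day exists (first-day convention)."""
    if not 1 <= day <= history.n_days:
        raise ValueError(f"day {day} outside history of {history.n_days} days")
    return float(history.stress()[day - 1])


def _lag_weights(t: int, n_days: int, d: float) -> np.ndarray:
    """(t-k)^(-d) for k = 1..n_days, zero for k >= t."""
    k = np.arange(1, n_days + 1)
    w = np.zeros(n_days)
    past = k < t
    w[past] = (t - k[past]) ** -d
    return w


def self_efficacy_gain(history: GoalHistory, day: int,
                       params: ImpulseParams) -> float:
    """Accumulated gain sigma(t) at day ``day`` from prior successful days.

    The sum runs over completed days k = 1..t-1 (a same-day impulse would
    have zero lag); failure-only days contribute nothing.
    """
    if day < 1:
        raise ValueError("day must be >= 1")
    w = _lag_weights(day, history.n_days, params.decay_d)
    impulses = np.where(history.success,
                        params.beta1 + params.gamma * history.stress(), 0.0)
    return float(np.dot(w, impulses))


def success_probability(theta: float, delta: float, day: int,
                        history: GoalHistory, params: ImpulseParams) -> float:
    """Probability of success on day ``day`` for a goal of difficulty delta."""
    if day < 1:
        raise ValueError("day must be >= 1")
    eta = (params.beta0 + theta - delta
           + params.alpha * day ** -params.decay_d
           + self_efficacy_gain(history, day, params))
    return float(expit(eta))


# ---------------------------------------------------------------------------
# fitting

def build_histories(records: pd.DataFrame,
                    difficulties: Mapping[str, float] | None = None,
                    n_days: int | None = None) -> dict[str, GoalHistory]:
    """Per-participant :class:`GoalHistory` from adherence records.

    Difficulties come from the ``difficulty`` column when present, else from
    the supplied exercise-difficulty map (e.g. a Rasch fit).
    """
    df = records.copy()
    if "difficulty" not in df.columns or df["difficulty"].isna().any():
        if difficulties is None:
            raise ValueError("records lack difficulties and no map supplied")
        df["difficulty"] = df["exercise_id"].astype(str).map(difficulties)
        if df["difficulty"].isna().any():
            bad = df.loc[df["difficulty"].isna(), "exercise_id"].unique()
            raise ValueError(f"missing difficulty for exercises: {bad[:5]}")
    if n_days is None:
        n_days = int(df["day"].max())
    out: dict[str, GoalHistory] = {}
    g = df.groupby("participant_id")
    for pid, sub in g:
        md = np.full(n_days, np.nan)
        sc = np.zeros(n_days, dtype=bool)
        agg = sub.groupby("day").agg(md=("difficulty", "mean"),
                                     sc=("success", "max"))
        md[agg.index.to_numpy() - 1] = agg["md"].to_numpy()
        sc[agg.index.to_numpy() - 1] = agg["sc"].to_numpy().astype(bool)
        out[str(pid)] = GoalHistory(md, sc)
    return out


@dataclass
class ImpulseFitReport:
    """Fitted parameters with pooled RMSE and approximate 95% CIs."""

    params: ImpulseParams
    rmse: float
    ci: dict[str, tuple[float, float]]
    n_points: int
    objective: str
    n_starts: int
    converged: bool
    pooled: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        p = asdict(self.params)
        return {"beta0": p["beta0"], "beta1": p["beta1"], "gamma": p["gamma"],
                "d": p["decay_d"], "alpha": p["alpha"], "rmse": self.rmse,
                "ci": {k: list(v) for k, v in self.ci.items()},
                "n_points": self.n_points, "objective": self.objective}


def _prepare_design(records: pd.DataFrame, rasch: RaschFit | None):
    df = records.copy()
    if rasch is not None:
        if "difficulty" not in df.columns or df["difficulty"].isna().any():
            df["difficulty"] = (df["exercise_id"].astype(str)
                                .map(rasch.difficulties))
        df["_theta"] = df["participant_id"].astype(str).map(rasch.abilities)
    elif "ability" in df.columns:
        df["_theta"] = df["ability"]
    else:
        raise ValueError("need a Rasch fit or an 'ability' column")
    if df["difficulty"].isna().any() or df["_theta"].isna().any():
        raise ValueError("missing difficulty or ability after mapping")
    n_days = int(df["day"].max())
    histories = build_histories(df, n_days=n_days)

    pids = df["participant_id"].astype(str).to_numpy()
    uniq = np.unique(pids)
    pid_code = pd.Categorical(pids, categories=uniq).codes
    # per-participant arrays over calendar days
    S = np.stack([histories[p].success for p in uniq])              # (P, D)
    Dl = np.stack([histories[p].stress() for p in uniq])            # (P, D)
    day = df["day"].to_numpy(dtype=int)
    base = df["_theta"].to_numpy(dtype=float) - df["difficulty"].to_numpy(float)
    y = df["success"].to_numpy(dtype=float)
    cond = (df["condition"].astype(str).to_numpy() if "condition" in df.columns
            else np.full(len(df), "all"))
    return df, uniq, pid_code, S, Dl, day, base, y, cond, n_days


def _trial_probs(x, pid_code, S, Dl, day, base, n_days):
    beta0, beta1, gamma, d, alpha = x
    kk = np.arange(1, n_days + 1)
    tt = np.arange(1, n_days + 1)
    lag = tt[:, None] - kk[None, :]
    W = np.where(lag > 0, np.maximum(lag, 1) ** -d, 0.0)   # (t, k)
    impulses = np.where(S, beta1 + gamma * Dl, 0.0)        # (P, k)
    sig = impulses @ W.T                                   # (P, t)
    eta = (beta0 + base + alpha * day ** -d
           + sig[pid_code, day - 1])
    return expit(eta)


def fit_impulse(records: pd.DataFrame, rasch: RaschFit | None = None,
                init: ImpulseParams | None = None,
                bounds: tuple | None = None,
                objective: str = "pooled",
                n_starts: int = 5, seed: int = 0,
                fix: Mapping[str, float] | None = None) -> ImpulseFitReport:
    """Fit the impulse model to adherence records by least squares.

    Residuals are observed-minus-predicted success rates pooled by
    condition and day (the scale on which fit quality is reported); pass
    ``objective="bernoulli"`` for a per-trial likelihood fit instead.
    ``fix`` pins named parameters (e.g. ``{"alpha": 0.0}``).

    Requires records spanning at least 2 conditions or at least 10 days.
    """
    (df, uniq, pid_code, S, Dl, day, base, y, cond,
     n_days) = _prepare_design(records, rasch)
    n_cond = len(np.unique(cond))
    if n_cond < 2 and n_days < 10:
        raise ValueError("need >= 2 conditions or >= 10 days of records")

    keys = pd.DataFrame({"condition": cond, "day": day})
    grp = keys.groupby(["condition", "day"], sort=True)
    codes = grp.ngroup().to_numpy()
    n_groups = codes.max() + 1
    if n_groups < 2:
        raise ValueError("degenerate pooling: fewer than 2 condition-day points")
    counts = np.bincount(codes, minlength=n_groups)
    obs_rate = np.bincount(codes, weights=y, minlength=n_groups) / counts

    if bounds is None:
        lower = np.array([-np.inf, -np.inf, 0.0, 1e-3, 0.0])
        upper = np.array([np.inf, np.inf, np.inf, 1.0, np.inf])
    else:
        lower, upper = (np.asarray(b, dtype=float) for b in bounds)
    names = ["beta0", "beta1", "gamma", "decay_d", "alpha"]
    fix = dict(fix or {})
    for k, v in fix.items():
        i = names.index(k)
        lower[i] = upper[i] = np.nan  # replaced below
    free = np.array([n not in fix for n in names])
    fixed_vals = np.array([fix.get(n, np.nan) for n in names])

    def expand(xf):
        x = fixed_vals.copy()
        x[free] = xf
        return x

    def residuals(xf):
        p = _trial_probs(expand(xf), pid_code, S, Dl, day, base, n_days)
        pred_rate = np.bincount(codes, weights=p, minlength=n_groups) / counts
        return obs_rate - pred_rate

    def nll(xf):
        p = np.clip(_trial_probs(expand(xf), pid_code, S, Dl, day, base,
                                 n_days), 1e-10, 1 - 1e-10)
        return -np.sum(y * np.log(p) + (1 - y) * np.log1p(-p))

    x0 = (init or ImpulseParams(beta0=0.0, beta1=0.0, gamma=0.1,
                                decay_d=0.7, alpha=0.0)).as_array()
    rng = np.random.default_rng(seed)
    lo_f, up_f = (np.where(np.isnan(lower), -np.inf, lower)[free],
                  np.where(np.isnan(upper), np.inf, upper)[free])
    starts = [np.clip(x0[free], np.where(np.isfinite(lo_f), lo_f, -2),
                      np.where(np.isfinite(up_f), up_f, 2))]
    for _ in range(n_starts - 1):
        jitter = rng.uniform(-0.3, 0.3, size=free.sum())
        starts.append(np.clip(starts[0] + jitter,
                              np.where(np.isfinite(lo_f), lo_f, -5),
                              np.where(np.isfinite(up_f), up_f, 5)))

    best = None
    if objective == "pooled":
        for s0 in starts:
            try:
                res = least_squares(residuals, s0, bounds=(lo_f, up_f),
                                    method="trf", xtol=1e-12, ftol=1e-12)
            except Exception:
                continue
            if best is None or res.cost < best.cost:
                best = res
        if best is None:
            raise RuntimeError("impulse fit failed to converge from any start")
        xf = best.x
        r = best.res = residuals(xf)
        rmse = float(np.sqrt(np.mean(r ** 2)))
        dof = max(n_groups - free.sum(), 1)
        s2 = np.sum(r ** 2) / dof
        J = best.jac
        cov_f = s2 * np.linalg.pinv(J.T @ J)
        converged = bool(best.success)
    elif objective == "bernoulli":
        for s0 in starts:
            res = minimize(nll, s0, method="L-BFGS-B",
                           bounds=list(zip(lo_f, up_f)))
            if best is None or res.fun < best.fun:
                best = res
        xf = best.x
        # report pooled RMSE regardless of objective
        r = residuals(xf)
        rmse = float(np.sqrt(np.mean(r ** 2)))
        cov_f = np.linalg.pinv(_numeric_hessian(nll, xf))
        converged = bool(best.success)
    else:
        raise ValueError(f"unknown objective {objective!r}")

    x = expand(xf)
    se = np.full(5, np.nan)
    se[free] = np.sqrt(np.maximum(np.diag(cov_f), 0.0))
    ci = {}
    report_names = ["beta0", "beta1", "gamma", "d", "alpha"]
    for i, n in enumerate(report_names):
        if np.isnan(se[i]):
            ci[n] = (x[i], x[i])
        else:
            lo_ci = x[i] - 1.96 * se[i]
            hi_ci = x[i] + 1.96 * se[i]
            lo_b = lower[i] if not np.isnan(lower[i]) else -np.inf
            up_b = upper[i] if not np.isnan(upper[i]) else np.inf
            ci[n] = (float(max(lo_ci, lo_b)), float(min(hi_ci, up_b)))
    if not converged:
        warnings.warn("impulse fit optimizer reported non-convergence",
                      UserWarning, stacklevel=2)

    pooled = (grp.size().reset_index(name="n")
              .assign(observed_rate=obs_rate,
                      predicted_rate=obs_rate - r))
    return ImpulseFitReport(params=ImpulseParams.from_array(x), rmse=rmse,
                            ci=ci, n_points=int(n_groups),
                            objective=objective, n_starts=n_starts,
                            converged=converged, pooled=pooled)


def _numeric_hessian(f, x, eps=1e-4):
    n = len(x)
    H = np.zeros((n, n))
    f0 = f(x)
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = eps
            ej = np.zeros(n); ej[j] = eps
            H[i, j] = H[j, i] = (f(x + ei + ej) - f(x + ei) - f(x + ej)
                                 + f0) / eps ** 2
    return H
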