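"""Rasch measurement of exercise difficulty and person ability.

The one-parameter IRT (Rasch) model puts persons and exercises on a shared
logit scale: the probability that person i succeeds at exercise j is

    Pr(X_ij = 1) = exp(theta_i - delta_j) / (1 + exp(theta_i - delta_j)).

Estimation treats person abilities as zero-mean random intercepts of a
logistic mixed model and exercise difficulties as fixed effects; the model
is fit without an intercept so the difficulties absorb it and the equation
above holds as printed.  Abilities are reported as the predicted random
effects (posterior means).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "RaschFit",
    "rasch_probability",
    "fit_rasch",
    "expert_rating_correlation",
]

REQUIRED_COLUMNS = ("participant_id", "exercise_id", "success")


@dataclass
class RaschFit:
    """Estimated person abilities and exercise difficulties (logits)."""

    abilities: dict[str, float]
    difficulties: dict[str, float]
    ability_variance: float
    convergence_info: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for m in (self.abilities, self.difficulties):
            for k, v in m.items():
                if not np.isfinite(v):
                    raise ValueError(f"non-finite estimate for {k!r}: {v}")
        if self.ability_variance < 0:
            raise ValueError("ability_variance must be non-negative")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"abilities": self.abilities,
                       "difficulties": self.difficulties,
                       "ability_variance": self.ability_variance,
                       "convergence_info": self.convergence_info}, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "RaschFit":
        with open(path) as fh:
            d = json.load(fh)
        return cls(abilities=d["abilities"], difficulties=d["difficulties"],
                   ability_variance=d["ability_variance"],
                   convergence_info=d.get("convergence_info", {}))


def rasch_probability(ability: float, difficulty: float) -> float:
    """Probability of success for ``ability`` theta on ``difficulty`` delta.

    The logistic of theta - delta; 0.5 exactly when theta equals delta.
    """
    if not (np.isfinite(ability) and np.isfinite(difficulty)):
        raise ValueError("ability and difficulty must be finite")
    return float(expit(ability - difficulty))


def _validate_records(records: pd.DataFrame) -> pd.DataFrame:
    df = records.copy()
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"adherence records missing columns: {missing}")
    if not set(np.unique(df["success"])) <= {0, 1}:
        raise ValueError("success must be coded 0/1")
    if df["participant_id"].nunique() < 2 or df["exercise_id"].nunique() < 2:
        raise ValueError("need >= 2 persons and >= 2 exercises")
    return df


def _fit_vb(y, X, Z, n_person):
    from statsmodels.genmod.bayes_mixed_glm import BinomialBayesMixedGLM
    model = BinomialBayesMixedGLM(
        y, X, Z, ident=np.zeros(n_person, dtype=int), vcp_p=2.0, fe_p=5.0)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        res = model.fit_vb()
        converged = not any("did not converge" in str(w.message) for w in caught)
    difficulties = -res.fe_mean
    abilities = res.vc_mean
    variance = float(np.exp(2.0 * res.vcp_mean[0]))
    return difficulties, abilities, variance, {"backend": "vb",
                                               "converged": bool(converged)}


def _fit_penalized(y, X, Z, n_person, max_iter=200, tol=1e-8):
    """Ridge-penalized joint logistic fit (Laplace-style fallback).

    Person effects get a quadratic penalty 1/(2 sigma^2) b'b; sigma^2 is
    updated from the penalized estimates plus their posterior curvature
    (an EM-like moment update), so abilities shrink like random effects.
    """
    D = np.hstack([X, Z])
    n_fe = X.shape[1]
    beta = np.zeros(D.shape[1])
    sigma2 = 1.0
    info = {"backend": "penalized", "converged": False}
    for _ in range(max_iter):
        eta = D @ beta
        mu = expit(eta)
        w = np.maximum(mu * (1 - mu), 1e-10)
        H = (D * w[:, None]).T @ D
        pen = np.zeros(D.shape[1])
        pen[n_fe:] = 1.0 / sigma2
        H[np.diag_indices_from(H)] += pen
        grad = D.T @ (y - mu) - pen * beta
        step = np.linalg.solve(H, grad)
        beta = beta + step
        # moment update of the random-effect variance
        Hinv_diag = np.diag(np.linalg.inv(H))[n_fe:]
        sigma2_new = float(np.mean(beta[n_fe:] ** 2 + Hinv_diag))
        moved = max(np.max(np.abs(step)), abs(sigma2_new - sigma2))
        sigma2 = max(sigma2_new, 1e-6)
        if moved < tol:
            info["converged"] = True
            break
    return -beta[:n_fe], beta[n_fe:], sigma2, info


def fit_rasch(records: pd.DataFrame, clamp: float = 6.0,
              backend: str = "vb") -> RaschFit:
    """Fit the Rasch model to dichotomous adherence records.

    Parameters
    ----------
    records
        DataFrame with columns ``participant_id``, ``exercise_id``,
        ``success`` (0/1).  Extra columns are ignored.
    clamp
        Bound (logits) applied to difficulties; exercises with complete
        separation (all successes or all failures) are assigned the bound
        directly, with a warning.
    backend
        ``"vb"`` for the variational-Bayes mixed GLM (default) or
        ``"penalized"`` for the ridge-penalized fallback.
    """
    df = _validate_records(records)
    persons = np.sort(df["participant_id"].unique())
    exercises = np.sort(df["exercise_id"].unique())

    # complete separation: clamp rather than estimate
    rates = df.groupby("exercise_id")["success"].mean()
    separated = {}
    for ex, r in rates.items():
        if r in (0.0, 1.0):
            separated[ex] = -clamp if r == 1.0 else clamp
    if separated:
        warnings.warn(
            f"{len(separated)} exercise(s) with complete separation; "
            f"difficulty clamped to +/-{clamp}: {sorted(separated)}",
            UserWarning, stacklevel=2)
    est_ex = [e for e in exercises if e not in separated]
    if len(est_ex) < 2:
        raise ValueError("fewer than 2 estimable (non-separated) exercises")

    sub = df[df["exercise_id"].isin(est_ex)]
    p_idx = pd.Categorical(sub["participant_id"], categories=persons).codes
    e_idx = pd.Categorical(sub["exercise_id"], categories=est_ex).codes
    y = sub["success"].to_numpy(dtype=float)
    X = np.zeros((len(sub), len(est_ex)))
    X[np.arange(len(sub)), e_idx] = 1.0
    Z = np.zeros((len(sub), len(persons)))
    Z[np.arange(len(sub)), p_idx] = 1.0

    if backend == "vb":
        delta, theta, var, info = _fit_vb(y, X, Z, len(persons))
    elif backend == "penalized":
        delta, theta, var, info = _fit_penalized(y, X, Z, len(persons))
    else:
        raise ValueError(f"unknown backend {backend!r}")

    if not np.all(np.isfinite(delta)) or not np.all(np.isfinite(theta)):
        raise RuntimeError(f"singular fit: non-finite estimates ({info})")

    n_clamped = int(np.sum(np.abs(delta) > clamp))
    if n_clamped:
        warnings.warn(f"{n_clamped} fitted difficulty value(s) clamped to "
                      f"+/-{clamp}", UserWarning, stacklevel=2)
    delta = np.clip(delta, -clamp, clamp)

    difficulties = {str(e): float(d) for e, d in zip(est_ex, delta)}
    difficulties.update({str(e): float(v) for e, v in separated.items()})
    info.update({"n_obs": int(len(df)), "n_persons": int(len(persons)),
                 "n_exercises": int(len(exercises)),
                 "n_separated": len(separated), "clamp": clamp})
    return RaschFit(
        abilities={str(p): float(t) for p, t in zip(persons, theta)},
        difficulties=difficulties,
        ability_variance=var,
        convergence_info=info,
    )


def expert_rating_correlation(fit: RaschFit | Mapping[str, float],
                              ratings: Mapping[str, float]) -> float:
    """Pearson correlation of estimated difficulties with external ratings.

    Computed over the exercises shared between the fit and the rating map;
    at least 3 shared exercises are required.
    """
    difficulties = fit.difficulties if isinstance(fit, RaschFit) else fit
    shared = sorted(set(difficulties) & set(ratings))
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared exercises, got {len(shared)}")
    d = np.array([difficulties[k] for k in shared])
    r = np.array([ratings[k] for k in shared])
    return float(np.corrcoef(d, r)[0, 1])
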