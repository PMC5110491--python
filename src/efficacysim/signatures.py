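"""Memory-signature curves and observed-vs-predicted evaluation.

Adherence that is driven by declarative memory should carry three
signatures: success rates rising with the count of past successful days
(frequency / practice), falling with the days elapsed since the last
success (lag / forgetting), and rising with the *stress* increment of the
assigned difficulty over the last achieved difficulty (blending).  The
pooling utilities aggregate observed and model-predicted success by
condition and day and score the agreement as an RMSE over those pooled
points.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .impulse import build_histories

__all__ = [
    "frequency_signature",
    "lag_signature",
    "stress_signature",
    "pool_by_condition_day",
    "rmse",
]

_KEYS = ["participant_id", "day", "exercise_id"]


def _check_sorted(records: pd.DataFrame) -> None:
    for _, sub in records.groupby("participant_id", sort=False):
        if not sub["day"].is_monotonic_increasing:
            raise ValueError("records must be sorted by day per participant")


def _success_days(records: pd.DataFrame) -> pd.DataFrame:
    """Per participant-day: any-success indicator and mean difficulty."""
    return (records.groupby(["participant_id", "day"])
            .agg(any_success=("success", "max"))
            .reset_index())


def frequency_signature(records: pd.DataFrame,
                        count_trials: bool = False) -> pd.DataFrame:
    """Success rate by the number of prior successful days.

    For each trial the covariate is the count of that participant's
    *earlier days* with at least one success (or, with
    ``count_trials=True``, of earlier individual successes); rates pool all
    participants' trials at each covariate value.  Returns columns ``x``,
    ``success_rate``, ``n``.
    """
    _check_sorted(records)
    parts = []
    for pid, sub in records.groupby("participant_id", sort=False):
        if count_trials:
            per_day = sub.groupby("day")["success"].sum()
        else:
            per_day = (sub.groupby("day")["success"].max() > 0).astype(int)
        prior = per_day.cumsum().shift(1, fill_value=0)
        parts.append(pd.DataFrame({"x": sub["day"].map(prior).to_numpy(),
                                   "success": sub["success"].to_numpy()}))
    allp = pd.concat(parts, ignore_index=True)
    out = (allp.groupby("x")["success"].agg(["mean", "size"])
           .reset_index()
           .rename(columns={"mean": "success_rate", "size": "n"}))
    return out


def lag_signature(records: pd.DataFrame) -> pd.DataFrame:
    """Success rate by days since the participant's last successful day.

    Trials before a participant's first success carry no lag and are
    excluded; the number excluded is reported in ``.attrs['n_excluded']``.
    """
    _check_sorted(records)
    parts = []
    n_excluded = 0
    for pid, sub in records.groupby("participant_id", sort=False):
        day_succ = sub.groupby("day")["success"].max()
        succ_days = day_succ[day_succ > 0].index.to_numpy()
        lags = []
        for d in sub["day"].to_numpy():
            prior = succ_days[succ_days < d]
            lags.append(d - prior[-1] if prior.size else np.nan)
        lags = np.asarray(lags, dtype=float)
        keep = np.isfinite(lags)
        n_excluded += int((~keep).sum())
        parts.append(pd.DataFrame({"x": lags[keep],
                                   "success": sub["success"].to_numpy()[keep]}))
    allp = pd.concat(parts, ignore_index=True)
    out = (allp.groupby("x")["success"].agg(["mean", "size"]).reset_index()
           .rename(columns={"mean": "success_rate", "size": "n"}))
    out["x"] = out["x"].astype(int)
    out.attrs["n_excluded"] = n_excluded
    return out


def stress_signature(records: pd.DataFrame,
                     bin_width: float = 0.25) -> pd.DataFrame:
    """Success rate by the stress overcome on the last successful day.

    For each trial the covariate is the stress increment Delta of the
    participant's most recent *successful* day before the trial — the rise
    in difficulty that participant last achieved.  Trials before any
    success carry no such increment and are excluded
    (``.attrs['n_excluded']``).  Stress values are binned at ``bin_width``
    logits; ``x`` is the bin center and the edges are stored in
    ``.attrs['bin_edges']``.
    """
    _check_sorted(records)
    if "difficulty" not in records.columns:
        raise ValueError("stress signature needs a difficulty column")
    histories = build_histories(records)
    rows = []
    n_excluded = 0
    for pid, sub in records.groupby("participant_id", sort=False):
        h = histories[str(pid)]
        stress = h.stress()
        succ_days = np.flatnonzero(h.success) + 1
        vals = []
        for d in sub["day"].to_numpy():
            prior = succ_days[succ_days < d]
            vals.append(stress[prior[-1] - 1] if prior.size else np.nan)
        vals = np.asarray(vals, dtype=float)
        keep = np.isfinite(vals)
        n_excluded += int((~keep).sum())
        rows.append(pd.DataFrame({
            "stress": vals[keep],
            "success": sub["success"].to_numpy()[keep]}))
    allp = pd.concat(rows, ignore_index=True)
    lo = np.floor(allp["stress"].min() / bin_width) * bin_width
    hi = np.ceil(allp["stress"].max() / bin_width) * bin_width
    edges = np.arange(lo, hi + bin_width, bin_width)
    if len(edges) < 2:
        edges = np.array([lo - bin_width / 2, lo + bin_width / 2])
    idx = np.clip(np.digitize(allp["stress"], edges) - 1, 0, len(edges) - 2)
    allp["x"] = (edges[idx] + edges[idx + 1]) / 2
    out = (allp.groupby("x")["success"].agg(["mean", "size"]).reset_index()
           .rename(columns={"mean": "success_rate", "size": "n"}))
    out.attrs["bin_edges"] = edges.tolist()
    out.attrs["n_excluded"] = n_excluded
    return out


def pool_by_condition_day(observed: pd.DataFrame,
                          predicted: pd.DataFrame,
                          predicted_col: str = "success") -> pd.DataFrame:
    """Observed and predicted success rates pooled by condition and day.

    Both frames must cover the same (participant, day, exercise) trials;
    the rate for a condition-day is successes divided by goals assigned.
    """
    obs_keys = observed[_KEYS].apply(tuple, axis=1)
    pred_keys = predicted[_KEYS].apply(tuple, axis=1)
    if sorted(obs_keys) != sorted(pred_keys):
        missing = set(obs_keys).symmetric_difference(pred_keys)
        raise ValueError(f"observed/predicted key mismatch, e.g. "
                         f"{sorted(missing)[:5]}")
    o = (observed.groupby(["condition", "day"])["success"].mean()
         .rename("observed_rate"))
    pred = predicted.merge(
        observed[_KEYS + ["condition"]].drop_duplicates(_KEYS),
        on=_KEYS, how="left", suffixes=("", "_obs"))
    cond_col = "condition_obs" if "condition_obs" in pred.columns else "condition"
    p = (pred.groupby([cond_col, "day"])[predicted_col].mean()
         .rename("predicted_rate"))
    p.index.names = ["condition", "day"]
    return pd.concat([o, p], axis=1).reset_index()


def rmse(pooled: pd.DataFrame) -> float:
    """Root-mean-square difference of observed and predicted pooled rates."""
    if len(pooled) == 0:
        raise ValueError("empty pooled table")
    r = pooled["observed_rate"] - pooled["predicted_rate"]
    return float(np.sqrt(np.mean(np.square(r))))
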