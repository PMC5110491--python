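"""ACT-R-style declarative memory with base-level learning and blended retrieval.

A memory is a store of *chunks*, each encoding one behavioral experience
(behavior label, difficulty, ability, effort, outcome) together with the
times at which it was experienced.  Chunk activation follows the base-level
learning equation

    B_i = ln( sum_j t_j^(-d) ) + beta_i,

where ``t_j`` is the lag (in days) since the j-th presentation and ``d`` is
the decay rate.  Activation noise is a zero-mean logistic draw with scale
``s``; retrieval probabilities are a softmax of activations at temperature
``s``; and *blending* returns the numeric slot value ``V`` minimizing

    sum_i P_i * (1 - Sim(V, V_i))^2

under a linear similarity ``Sim(V, V_i) = 1 - |V - V_i| / range`` clipped to
[0, 1].  When no clipping is active the minimizer is the retrieval-
probability-weighted mean of the stored values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "MemoryParams",
    "ExperienceChunk",
    "MemoryStore",
    "RetrievalFailure",
    "base_level_activation",
    "activation",
    "retrieval_probabilities",
    "blend",
    "blended_retrieve",
]

SUCCESS = "success"
FAILURE = "failure"

#: lag floor in days: same-moment presentations would give 0^(-d)
MIN_LAG = 0.5


class RetrievalFailure(Exception):
    """No chunk matches the hard constraints of a blending request."""


@dataclass
class MemoryParams:
    """Subsymbolic memory parameters.

    decay_d
        Base-level decay rate ``d`` in (0, 1); 0.5 is the community default.
    noise_s
        Activation-noise / softmax scale ``s`` (> 0); 0.25 is the community
        default.  Tests may pass values near 0 to probe the noiseless limit.
    similarity_scale
        Range constant of the linear similarity function (> 0).  4 logits
        comfortably covers the difficulty/ability range of these data.
    retrieval_threshold
        Minimum activation for a chunk to enter blending, or ``None`` to let
        every constraint-matching chunk participate (the default).
    min_lag
        Floor on presentation lags, in days.
    """

    decay_d: float = 0.5
    noise_s: float = 0.25
    similarity_scale: float = 4.0
    retrieval_threshold: float | None = None
    min_lag: float = MIN_LAG

    def __post_init__(self) -> None:
        if not 0.0 < self.decay_d < 1.0:
            raise ValueError(f"decay_d must be in (0, 1), got {self.decay_d}")
        if not self.noise_s > 0.0:
            raise ValueError(f"noise_s must be > 0, got {self.noise_s}")
        if not self.similarity_scale > 0.0:
            raise ValueError("similarity_scale must be > 0")


@dataclass
class ExperienceChunk:
    """One remembered behavior episode.

    ``difficulty``, ``ability`` and ``effort`` live on the logit scale;
    ``outcome`` is ``"success"`` or ``"failure"``; ``presentation_times`` is
    the non-decreasing list of event times in days; ``offset`` is the
    constant base-level offset beta_i.
    """

    behavior: str
    difficulty: float
    ability: float
    effort: float
    outcome: str
    presentation_times: list[float] = field(default_factory=list)
    offset: float = 0.0

    def __post_init__(self) -> None:
        if self.outcome not in (SUCCESS, FAILURE):
            raise ValueError(f"outcome must be '{SUCCESS}' or '{FAILURE}'")
        if not self.presentation_times:
            raise ValueError("presentation_times must be non-empty")
        t = np.asarray(self.presentation_times, dtype=float)
        if np.any(np.diff(t) < 0):
            raise ValueError("presentation_times must be non-decreasing")
        if self.effort < 0:
            raise ValueError("effort must be non-negative")


def base_level_activation(chunk: ExperienceChunk, now: float,
                          params: MemoryParams) -> float:
    """Base-level activation B = ln(sum of lag^(-d)) + offset at time ``now``."""
    lags = now - np.asarray(chunk.presentation_times, dtype=float)
    if np.any(lags <= 0):
        raise ValueError("now must be later than every presentation time")
    lags = np.maximum(lags, params.min_lag)
    return float(np.log(np.sum(lags ** -params.decay_d)) + chunk.offset)


def activation(chunk: ExperienceChunk, now: float, params: MemoryParams,
               rng: np.random.Generator) -> float:
    """Noisy activation A = B + eps, eps ~ Logistic(0, noise_s)."""
    eps = rng.logistic(loc=0.0, scale=params.noise_s)
    return base_level_activation(chunk, now, params) + eps


def retrieval_probabilities(activations: Sequence[float],
                            noise_s: float) -> np.ndarray:
    """Softmax retrieval probabilities P_i = exp(A_i/s) / sum_j exp(A_j/s)."""
    a = np.asarray(activations, dtype=float)
    if a.size == 0:
        raise ValueError("activations must be non-empty")
    if not np.all(np.isfinite(a)):
        raise ValueError("activations must be finite")
    if not noise_s > 0:
        raise ValueError("noise_s must be > 0")
    z = (a - a.max()) / noise_s
    w = np.exp(z)
    return w / w.sum()


def _blend_objective(v: float, values: np.ndarray, probs: np.ndarray,
                     scale: float) -> float:
    sim = 1.0 - np.abs(v - values) / scale
    sim = np.clip(sim, 0.0, 1.0)
    return float(np.sum(probs * (1.0 - sim) ** 2))


def blend(values: Sequence[float], probabilities: Sequence[float],
          similarity_scale: float) -> float:
    """Blended (compromise) value minimizing sum_i P_i (1 - Sim(V, V_i))^2.

    With the linear similarity and no clipping active, the minimizer is the
    probability-weighted mean; when the value spread exceeds the similarity
    range the clipped objective is minimized numerically over
    [min(values), max(values)].
    """
    v = np.asarray(values, dtype=float)
    p = np.asarray(probabilities, dtype=float)
    if v.size == 0 or v.shape != p.shape:
        raise ValueError("values and probabilities must be equal-length, non-empty")
    if similarity_scale <= 0:
        raise ValueError("similarity_scale must be > 0")
    wm = float(np.dot(p, v))
    if v.max() - v.min() <= similarity_scale:
        # no clipping possible anywhere in [min, max]: exact closed form
        return wm
    # clipped objective: piecewise quadratic; grid + local refinement
    lo, hi = float(v.min()), float(v.max())
    grid = np.linspace(lo, hi, 512)
    sim = np.clip(1.0 - np.abs(grid[:, None] - v[None, :]) / similarity_scale, 0.0, 1.0)
    obj = ((1.0 - sim) ** 2 @ p)
    best = grid[int(np.argmin(obj))]
    from scipy.optimize import minimize_scalar
    span = (hi - lo) / 511
    res = minimize_scalar(
        _blend_objective, bounds=(max(lo, best - span), min(hi, best + span)),
        args=(v, p, similarity_scale), method="bounded",
        options={"xatol": 1e-8})
    return float(res.x) if res.fun <= _blend_objective(best, v, p, similarity_scale) else float(best)


class MemoryStore:
    """Declarative memory: a growing collection of experience chunks.

    Slot values are mirrored into numpy arrays so that the activations of
    thousands of chunks can be computed per retrieval without a Python loop.
    """

    def __init__(self, params: MemoryParams | None = None) -> None:
        self.params = params if params is not None else MemoryParams()
        self.chunks: list[ExperienceChunk] = []
        self.current_time: float = -np.inf
        self._cache_valid = False
        self._flat_times: np.ndarray | None = None
        self._flat_idx: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.chunks)

    # -- mutation ----------------------------------------------------------

    def add_experience(self, chunk: ExperienceChunk, *,
                       merge_identical: bool = True) -> int:
        """Insert a chunk (or reinforce an identical one) and return its index.

        A chunk whose slot values all equal an existing chunk's is merged:
        its presentation times are appended to the existing chunk, which is
        the architecture's account of repetition strengthening one memory.
        """
        t0 = chunk.presentation_times[0]
        if t0 < self.current_time:
            raise ValueError(
                f"time regression: chunk at t={t0} before memory time "
                f"{self.current_time}")
        if merge_identical:
            for i, c in enumerate(self.chunks):
                if (c.behavior == chunk.behavior
                        and c.outcome == chunk.outcome
                        and c.difficulty == chunk.difficulty
                        and c.ability == chunk.ability
                        and c.effort == chunk.effort
                        and c.offset == chunk.offset):
                    for t in chunk.presentation_times:
                        self.reinforce(i, t)
                    return i
        self.chunks.append(chunk)
        self.current_time = max(self.current_time, chunk.presentation_times[-1])
        self._cache_valid = False
        return len(self.chunks) - 1

    def reinforce(self, chunk_id: int, time: float) -> None:
        """Append a presentation of an existing chunk at ``time``."""
        if time < self.current_time:
            raise ValueError("time regression in reinforce")
        self.chunks[chunk_id].presentation_times.append(time)
        self.current_time = max(self.current_time, time)
        self._cache_valid = False

    # -- vectorized reads --------------------------------------------------

    def _rebuild_cache(self) -> None:
        times, idx = [], []
        for i, c in enumerate(self.chunks):
            times.extend(c.presentation_times)
            idx.extend([i] * len(c.presentation_times))
        self._flat_times = np.asarray(times, dtype=float)
        self._flat_idx = np.asarray(idx, dtype=np.intp)
        self._slot = {
            "difficulty": np.array([c.difficulty for c in self.chunks]),
            "ability": np.array([c.ability for c in self.chunks]),
            "effort": np.array([c.effort for c in self.chunks]),
        }
        self._offsets = np.array([c.offset for c in self.chunks])
        self._success = np.array([c.outcome == SUCCESS for c in self.chunks])
        self._behavior = np.array([c.behavior for c in self.chunks], dtype=object)
        self._cache_valid = True

    def base_level_activations(self, now: float) -> np.ndarray:
        """Base-level activation of every chunk at time ``now``."""
        if not self._cache_valid:
            self._rebuild_cache()
        lags = now - self._flat_times
        if np.any(lags <= 0):
            raise ValueError("now must be later than every presentation time")
        lags = np.maximum(lags, self.params.min_lag)
        sums = np.bincount(self._flat_idx, weights=lags ** -self.params.decay_d,
                           minlength=len(self.chunks))
        return np.log(sums) + self._offsets

    def match(self, query: Mapping[str, object]) -> np.ndarray:
        """Boolean mask of chunks matching hard slot constraints.

        Supported keys: ``outcome`` and ``behavior``.  Numeric slots are
        soft-matched through similarity penalties, not hard constraints.
        """
        if not self._cache_valid:
            self._rebuild_cache()
        mask = np.ones(len(self.chunks), dtype=bool)
        for key, val in query.items():
            if key == "outcome":
                mask &= self._success if val == SUCCESS else ~self._success
            elif key == "behavior":
                mask &= self._behavior == val
            else:
                raise KeyError(f"unsupported hard constraint: {key}")
        return mask

    def slot_values(self, slot: str) -> np.ndarray:
        if not self._cache_valid:
            self._rebuild_cache()
        return self._slot[slot]

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "params": asdict(self.params),
            "current_time": self.current_time,
            "chunks": [asdict(c) for c in self.chunks],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "MemoryStore":
        store = cls(MemoryParams(**d["params"]))
        for cd in d["chunks"]:
            store.chunks.append(ExperienceChunk(**cd))
        store.current_time = d["current_time"]
        store._cache_valid = False
        return store


def blended_retrieve(store: MemoryStore, query: Mapping[str, object],
                     target_slot: str, now: float, params: MemoryParams,
                     rng: np.random.Generator,
                     activation_penalty: np.ndarray | None = None) -> float:
    """Blend the ``target_slot`` values of the chunks matching ``query``.

    Activations = base level + logistic noise (one draw per matching chunk
    per request) minus an optional per-chunk penalty (used for similarity-
    conditioned recall).  Raises :class:`RetrievalFailure` when nothing
    matches, leaving the fallback to the caller.
    """
    mask = store.match(query)
    if not mask.any():
        raise RetrievalFailure(f"no chunk matches {dict(query)}")
    base = store.base_level_activations(now)[mask]
    noise = rng.logistic(loc=0.0, scale=params.noise_s, size=base.size)
    act = base + noise
    if activation_penalty is not None:
        act = act - np.asarray(activation_penalty, dtype=float)[mask]
    if params.retrieval_threshold is not None:
        keep = act >= params.retrieval_threshold
        if not keep.any():
            raise RetrievalFailure("all matching chunks below retrieval threshold")
        act = act[keep]
        values = store.slot_values(target_slot)[mask][keep]
    else:
        values = store.slot_values(target_slot)[mask]
    probs = retrieval_probabilities(act, params.noise_s)
    return blend(values, probs, params.similarity_scale)
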