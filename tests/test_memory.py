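"""Declarative-memory unit and property tests: base-level learning,
softmax retrieval, and blended retrieval against a brute-force oracle."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from efficacysim.memory import (ExperienceChunk, MemoryParams, MemoryStore,
                                RetrievalFailure, activation,
                                base_level_activation, blend,
                                blended_retrieve, retrieval_probabilities,
                                _blend_objective)

P = MemoryParams()


def chunk(times, offset=0.0, outcome="success", difficulty=0.3):
    return ExperienceChunk(behavior="b", difficulty=difficulty, ability=0.0,
                           effort=0.1, outcome=outcome,
                           presentation_times=list(times), offset=offset)


class TestBaseLevelActivation:
    @pytest.mark.parametrize("times, now, expected", [
        ([0.0], 1.0, 0.0),                          # single unit lag
        ([0.0, 1.0], 2.0, np.log(1 + 2 ** -0.5)),   # lags 1 and 2 days
    ])
    def test_printed_formula_values(self, times, now, expected):
        assert base_level_activation(chunk(times), now, P) == pytest.approx(
            expected, abs=1e-12)

    def test_offset_shifts_additively(self):
        assert base_level_activation(chunk([0.0], offset=0.7), 1.0, P) == (
            pytest.approx(0.7))

    def test_extra_presentation_increases_activation(self):
        base = base_level_activation(chunk([0.0]), 3.0, P)
        more = base_level_activation(chunk([0.0, 1.0]), 3.0, P)
        assert more > base

    def test_now_before_presentation_rejected(self):
        with pytest.raises(ValueError):
            base_level_activation(chunk([2.0]), 1.0, P)

    @given(st.lists(st.floats(0, 10), min_size=1, max_size=6).map(sorted),
           st.floats(0.5, 20))
    @settings(max_examples=60, deadline=None)
    def test_power_law_of_forgetting(self, times, dt):
        """Activation strictly decreases as time passes with fixed history."""
        c = chunk(times)
        now = times[-1] + 1.0
        assert (base_level_activation(c, now + dt, P)
                < base_level_activation(c, now, P))


class TestNoisyActivation:
    def test_noiseless_limit_equals_base_level(self):
        p = MemoryParams(noise_s=1e-12)
        got = activation(chunk([0.0]), 1.0, p, np.random.default_rng(0))
        assert got == pytest.approx(0.0, abs=1e-9)

    def test_deterministic_given_rng_state(self):
        a = activation(chunk([0.0]), 1.0, P, np.random.default_rng(42))
        b = activation(chunk([0.0]), 1.0, P, np.random.default_rng(42))
        assert a == b

    def test_noise_is_zero_mean(self):
        rng = np.random.default_rng(3)
        draws = [activation(chunk([0.0]), 1.0, P, rng) for _ in range(10_000)]
        se = np.std(draws) / np.sqrt(len(draws))
        assert abs(np.mean(draws)) < 3 * se


class TestRetrievalProbabilities:
    def test_two_equal_activations_split_evenly(self):
        np.testing.assert_allclose(retrieval_probabilities([1.2, 1.2], 0.25),
                                   [0.5, 0.5])

    def test_unit_temperature_softmax_value(self):
        p = retrieval_probabilities([1.0, 0.0], 1.0)
        np.testing.assert_allclose(
            p, [np.e / (np.e + 1), 1 / (np.e + 1)], atol=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            retrieval_probabilities([], 1.0)

    @given(st.lists(st.floats(-50, 50), min_size=1, max_size=10),
           st.floats(0.05, 5), st.floats(-20, 20))
    @settings(max_examples=80, deadline=None)
    def test_normalization_and_shift_invariance(self, acts, s, shift):
        p = retrieval_probabilities(acts, s)
        assert np.sum(p) == pytest.approx(1.0, abs=1e-12)
        shifted = retrieval_probabilities([a + shift for a in acts], s)
        np.testing.assert_allclose(p, shifted, atol=1e-9)


class TestBlend:
    def test_single_value_is_identity(self):
        assert blend([0.7], [1.0], 4.0) == pytest.approx(0.7)

    def test_symmetric_values_blend_to_zero(self):
        assert blend([-1.0, 1.0], [0.5, 0.5], 4.0) == pytest.approx(0.0)

    def test_weighted_mean_case(self):
        assert blend([0.0, 0.5, 1.0], [0.2, 0.3, 0.5], 4.0) == (
            pytest.approx(0.65))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            blend([1.0, 2.0], [1.0], 4.0)

    @given(st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None)
    def test_matches_grid_search_of_objective(self, seed):
        """Blend equals the argmin of the printed objective (oracle)."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 8))
        vals = rng.uniform(-2, 2, n)
        probs = rng.dirichlet(np.ones(n))
        scale = float(rng.uniform(0.5, 6.0))
        got = blend(vals, probs, scale)
        grid = np.linspace(vals.min(), vals.max(), 4001)
        objs = [_blend_objective(v, vals, probs, scale) for v in grid]
        best = grid[int(np.argmin(objs))]
        assert got == pytest.approx(best, abs=1e-3)
        assert vals.min() - 1e-12 <= got <= vals.max() + 1e-12


class TestStore:
    def test_add_then_retrieve(self):
        store = MemoryStore(P)
        store.add_experience(chunk([0.0], difficulty=0.4))
        got = blended_retrieve(store, {"outcome": "success"}, "difficulty",
                               1.0, P, np.random.default_rng(0))
        assert got == pytest.approx(0.4)

    def test_reinforce_increases_activation(self):
        s1, s2 = MemoryStore(P), MemoryStore(P)
        i = s1.add_experience(chunk([0.0]))
        s2.add_experience(chunk([0.0]))
        s1.reinforce(i, 1.0)
        assert s1.base_level_activations(2.0)[0] > (
            s2.base_level_activations(2.0)[0])

    def test_identical_chunks_merge_presentations(self):
        store = MemoryStore(P)
        store.add_experience(chunk([1.0]))
        store.add_experience(chunk([2.0]))
        assert len(store) == 1
        expected = np.log(2.0 ** -0.5 + 1.0 ** -0.5)
        assert store.base_level_activations(3.0)[0] == pytest.approx(expected)

    def test_time_regression_rejected(self):
        store = MemoryStore(P)
        store.add_experience(chunk([5.0]))
        with pytest.raises(ValueError):
            store.add_experience(chunk([1.0]))

    def test_no_match_raises_retrieval_failure(self):
        store = MemoryStore(P)
        store.add_experience(chunk([0.0], outcome="failure"))
        with pytest.raises(RetrievalFailure):
            blended_retrieve(store, {"outcome": "success"}, "difficulty",
                             1.0, P, np.random.default_rng(0))

    def test_json_round_trip(self):
        store = MemoryStore(P)
        store.add_experience(chunk([0.0]))
        store.add_experience(chunk([1.0], outcome="failure", difficulty=-0.2))
        back = MemoryStore.from_dict(store.to_dict())
        np.testing.assert_allclose(back.base_level_activations(2.0),
                                   store.base_level_activations(2.0))


def test_blended_retrieve_matches_compositional_recomputation():
    """End-to-end blending equals composing the three primitive steps."""
    rng = np.random.default_rng(7)
    store = MemoryStore(P)
    for i in range(50):
        store.add_experience(ExperienceChunk(
            behavior="b", difficulty=float(rng.uniform(-1, 1)),
            ability=0.0, effort=0.1,
            outcome="success" if rng.random() < 0.7 else "failure",
            presentation_times=[float(i * 0.1)]), merge_identical=False)
    now = 10.0
    got = blended_retrieve(store, {"outcome": "success"}, "difficulty", now,
                           P, np.random.default_rng(99))
    # independent recomputation with the same noise stream
    mask = store.match({"outcome": "success"})
    base = store.base_level_activations(now)[mask]
    noise = np.random.default_rng(99).logistic(0, P.noise_s, base.size)
    probs = retrieval_probabilities(base + noise, P.noise_s)
    expected = blend(store.slot_values("difficulty")[mask], probs,
                     P.similarity_scale)
    assert got == pytest.approx(expected, abs=1e-12)
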