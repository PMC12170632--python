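"""Similarity metrics and optimal synergy matching."""

import itertools

import numpy as np
import pytest

from musclesyn import (
    compare_decompositions,
    match_synergies,
    pearson_similarity,
    scalar_product_similarity,
)
from musclesyn.compare import match_synergies_bruteforce, per_muscle_similarity
from musclesyn.containers import SynergySet
from musclesyn.errors import DomainError, UndefinedSimilarityError


def synergy_set(w, labels=None, c=None):
    w = np.asarray(w, dtype=float)
    if labels is None:
        labels = [f"m{i}" for i in range(w.shape[0])]
    if c is None:
        c = np.abs(np.sin(np.linspace(0, 3, 20)))[None, :] * np.ones((w.shape[1], 1))
        c = c + np.arange(w.shape[1])[:, None] * 0.3
    return SynergySet(w=w, c=c, muscle_labels=labels)


class TestScalarProduct:
    def test_parallel_is_one(self, rng):
        u = rng.random(10) + 0.1
        assert scalar_product_similarity(u, 3.0 * u) == pytest.approx(1.0)

    def test_orthogonal_is_zero(self):
        assert scalar_product_similarity([1, 0], [0, 1]) == pytest.approx(0.0)

    def test_hand_value(self):
        assert scalar_product_similarity([1, 1], [1, 0]) == pytest.approx(1 / np.sqrt(2))

    def test_zero_vector_rejected(self):
        with pytest.raises(UndefinedSimilarityError):
            scalar_product_similarity([0, 0], [1, 0])

    def test_bounds_on_random_nonnegative_pairs(self, rng):
        for _ in range(500):
            u = rng.random(12)
            v = rng.random(12)
            s = scalar_product_similarity(u, v)
            assert 0.0 <= s <= 1.0

    def test_scale_invariance(self, rng):
        u, v = rng.random(6) + 0.1, rng.random(6) + 0.1
        assert scalar_product_similarity(u, v) == pytest.approx(
            scalar_product_similarity(5 * u, 0.2 * v)
        )


class TestPearson:
    def test_affine_is_one(self):
        x = np.array([1.0, 2.0, 5.0, 7.0])
        assert pearson_similarity(x, 2 * x + 1) == pytest.approx(1.0)

    def test_negated_is_minus_one(self):
        x = np.array([1.0, 2.0, 3.0])
        assert pearson_similarity(x, -x) == pytest.approx(-1.0)

    def test_hand_value(self):
        assert pearson_similarity([1, 2, 3], [1, 3, 2]) == pytest.approx(0.5)

    def test_constant_rejected(self):
        with pytest.raises(UndefinedSimilarityError):
            pearson_similarity([1, 1, 1], [1, 2, 3])


class TestMatching:
    def test_recovers_column_permutation(self, rng):
        w = rng.random((8, 3)) + 0.05
        a = synergy_set(w)
        b = synergy_set(w[:, [2, 0, 1]])
        pairs = match_synergies(a, b)
        assert pairs == [(0, 1), (1, 2), (2, 0)]
        for i, j in pairs:
            assert scalar_product_similarity(a.w[:, i], b.w[:, j]) == pytest.approx(1.0)

    def test_single_component(self, rng):
        a = synergy_set(rng.random((5, 1)) + 0.1)
        b = synergy_set(rng.random((5, 1)) + 0.1)
        assert match_synergies(a, b) == [(0, 0)]

    def test_assignment_beats_greedy_trap(self):
        # Column 0 of a is most similar to column 0 of b, but the optimal
        # assignment must give it up to maximize the total.
        a = synergy_set(np.array([[1.0, 0.9, 0.0], [0.1, 1.0, 0.0], [0.0, 0.1, 1.0]]).T)
        b = synergy_set(np.array([[1.0, 0.2, 0.0], [0.9, 1.0, 0.1], [0.0, 0.0, 1.0]]).T)
        pairs = match_synergies(a, b)
        assert pairs == match_synergies_bruteforce(a, b)

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(20):
            a = synergy_set(rng.random((7, 4)) + 0.01)
            b = synergy_set(rng.random((7, 4)) + 0.01)
            fast = match_synergies(a, b)
            slow = match_synergies_bruteforce(a, b)
            total = lambda pairs: sum(
                scalar_product_similarity(a.w[:, i], b.w[:, j]) for i, j in pairs
            )
            assert total(fast) == pytest.approx(total(slow))


class TestPerMuscle:
    def test_identical_sets_all_one(self, rng):
        w = rng.random((6, 3)) + 0.05
        a = synergy_set(w)
        vals = per_muscle_similarity(a, a, [(i, i) for i in range(3)])
        assert np.allclose(vals, 1.0)

    def test_swapped_weights_penalize_one_muscle(self):
        w_a = np.array([[1.0, 0.0], [0.3, 0.7], [0.2, 0.9]])
        w_b = w_a.copy()
        w_b[0] = [0.0, 1.0]  # muscle 0's weights swapped between synergies
        a, b = synergy_set(w_a), synergy_set(w_b)
        vals = per_muscle_similarity(a, b, [(0, 0), (1, 1)])
        assert vals[0] < 1.0 - 1e-9
        assert np.allclose(vals[1:], 1.0)

    def test_disjoint_profiles_zero(self):
        a = synergy_set(np.array([[1.0, 0.0], [0.5, 0.5]]))
        b = synergy_set(np.array([[0.0, 1.0], [0.5, 0.5]]))
        vals = per_muscle_similarity(a, b, [(0, 0), (1, 1)])
        assert vals[0] == pytest.approx(0.0)


class TestReport:
    def test_self_comparison_all_ones(self, rng):
        w = rng.random((6, 3)) + 0.05
        c = rng.random((3, 25)) + 0.05
        a = synergy_set(w, c=c)
        rep = compare_decompositions(a, a)
        assert np.allclose(rep.w_similarity, 1.0)
        assert np.allclose(rep.c_similarity, 1.0)
        assert np.allclose(rep.per_muscle, 1.0)

    def test_symmetry_up_to_transposed_matching(self, rng):
        a = synergy_set(rng.random((6, 3)) + 0.05, c=rng.random((3, 25)) + 0.05)
        b = synergy_set(rng.random((6, 3)) + 0.05, c=rng.random((3, 25)) + 0.05)
        ab = compare_decompositions(a, b)
        ba = compare_decompositions(b, a)
        assert sorted((j, i) for i, j in ab.matching) == sorted(ba.matching)
        assert np.allclose(sorted(ab.w_similarity), sorted(ba.w_similarity))

    def test_default_cohort_similarity_band(self, small_cohort):
        """EMG vs model weights agree within the generator's design band."""
        from musclesyn import nmf_decompose
        from musclesyn.order import concatenate_trials

        emg = [t for t in small_cohort if t.modality == "emg" and t.subject_id == "S01"]
        mod = [t for t in small_cohort if t.modality == "model" and t.subject_id == "S01"]
        sa = nmf_decompose(concatenate_trials(emg), 3, n_restarts=20, seed=0)
        sb = nmf_decompose(concatenate_trials(mod), 3, n_restarts=20, seed=0)
        rep = compare_decompositions(sa, sb)
        assert 0.75 <= rep.summary["w_mean"] <= 1.0
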