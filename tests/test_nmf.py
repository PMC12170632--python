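"""Factorization contracts: exact recovery, monotonicity, normalization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from musclesyn import (
    SynthConfig,
    generate_trial,
    global_vaf,
    local_vaf,
    make_ground_truth,
    nmf_decompose,
    normalize_synergies,
    reconstruct,
)
from musclesyn.containers import SynergySet
from musclesyn.errors import DomainError, InvalidOrderError, UndefinedVAFError


class TestDecompose:
    def test_rank_one_exact(self, rng):
        u = rng.random(8)
        v = rng.random(30)
        m = np.outer(u, v)
        s = nmf_decompose(m, 1, n_restarts=10, max_iter=500, seed=0)
        err = np.linalg.norm(m - reconstruct(s))
        assert err < 1e-8 * np.linalg.norm(m)

    def test_all_zero_matrix(self):
        s = nmf_decompose(np.zeros((4, 10)), 2, n_restarts=2, seed=0)
        assert s.objective == pytest.approx(0.0)
        assert np.allclose(reconstruct(s), 0.0)

    def test_full_row_rank_near_exact(self, rng):
        m = rng.random((6, 40))
        s = nmf_decompose(m, 6, n_restarts=30, max_iter=2000, tol=1e-12, seed=0)
        assert global_vaf(m, reconstruct(s)) >= 0.999

    def test_objective_monotone_nonincreasing(self, rng):
        m = rng.random((10, 50))
        s = nmf_decompose(m, 3, n_restarts=5, seed=0)
        h = s.objective_history
        assert np.all(np.diff(h) <= 1e-9 * h[0])

    def test_deterministic_given_seed(self, rng):
        m = rng.random((8, 20))
        a = nmf_decompose(m, 2, n_restarts=5, seed=11)
        b = nmf_decompose(m, 2, n_restarts=5, seed=11)
        assert np.array_equal(a.w, b.w) and np.array_equal(a.c, b.c)

    def test_negative_input_rejected(self):
        with pytest.raises(DomainError):
            nmf_decompose(np.array([[1.0, -0.1]]), 1)

    def test_k_out_of_range_rejected(self, rng):
        with pytest.raises(InvalidOrderError):
            nmf_decompose(rng.random((4, 10)), 5)

    def test_recovers_ground_truth_weights_noiseless(self):
        """Parameter recovery: matched column cosines > 0.99 without noise."""
        from musclesyn.compare import scalar_product_similarity
        from scipy.optimize import linear_sum_assignment

        cfg = SynthConfig(snr_db=np.inf)
        gt = make_ground_truth(cfg)
        m = generate_trial(gt, cfg, "emg", trial_seed=2)
        s = nmf_decompose(m, 3, n_restarts=50, max_iter=500, seed=0)
        sim = np.array(
            [
                [scalar_product_similarity(gt.w_true[:, i], s.w[:, j]) for j in range(3)]
                for i in range(3)
            ]
        )
        rows, cols = linear_sum_assignment(-sim)
        assert np.all(sim[rows, cols] > 0.99)

    def test_scale_equivariance(self, rng):
        """Scaling M by gamma leaves normalized W fixed and scales C."""
        m = rng.random((8, 30))
        a = nmf_decompose(m, 2, n_restarts=5, max_iter=300, seed=4)
        b = nmf_decompose(3.0 * m, 2, n_restarts=5, max_iter=300, seed=4)
        assert np.allclose(a.w, b.w, atol=1e-6)
        assert np.allclose(3.0 * a.c, b.c, rtol=1e-5)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_factors_never_negative(self, seed):
        rng = np.random.default_rng(seed)
        m = rng.random((6, 15))
        s = nmf_decompose(m, 2, n_restarts=2, max_iter=30, seed=seed)
        assert np.all(s.w >= 0) and np.all(s.c >= 0)


class TestVaf:
    def test_exact_reconstruction_is_one(self, rng):
        m = rng.random((3, 5))
        assert global_vaf(m, m) == pytest.approx(1.0)
        assert np.allclose(local_vaf(m, m), 1.0)

    def test_zero_reconstruction_is_zero(self, rng):
        m = rng.random((3, 5))
        assert global_vaf(m, np.zeros_like(m)) == pytest.approx(0.0)

    def test_hand_value(self):
        assert global_vaf(np.array([[3.0, 4.0]]), np.array([[3.0, 0.0]])) == pytest.approx(0.36)

    def test_local_rowwise(self):
        m = np.array([[3.0, 4.0], [1.0, 2.0]])
        m_hat = np.array([[3.0, 9.0], [1.0, 2.0]])
        lv = local_vaf(m, m_hat)
        assert lv[0] == pytest.approx(0.0)
        assert lv[1] == pytest.approx(1.0)

    def test_zero_row_flagged_not_raised(self):
        m = np.array([[0.0, 0.0], [1.0, 1.0]])
        lv = local_vaf(m, m)
        assert np.isnan(lv[0]) and lv[1] == pytest.approx(1.0)

    def test_zero_matrix_undefined(self):
        with pytest.raises(UndefinedVAFError):
            global_vaf(np.zeros((2, 2)), np.zeros((2, 2)))


class TestNormalize:
    def test_product_invariant(self, rng):
        w = rng.random((6, 3)) * 5
        c = rng.random((3, 20))
        s = SynergySet(w=w, c=c, muscle_labels=[f"m{i}" for i in range(6)])
        ns = normalize_synergies(s)
        assert np.allclose(reconstruct(ns), w @ c, atol=1e-12)
        assert np.allclose(np.linalg.norm(ns.w, axis=0), 1.0)

    def test_zero_column_flagged(self):
        w = np.array([[1.0, 0.0], [0.0, 0.0]])
        c = np.ones((2, 4))
        s = normalize_synergies(SynergySet(w=w, c=c, muscle_labels=["a", "b"]))
        assert s.zero_columns == (1,)

    def test_idempotent_on_normalized(self, rng):
        w = rng.random((5, 2))
        w /= np.linalg.norm(w, axis=0)
        s = SynergySet(w=w, c=rng.random((2, 9)), muscle_labels=list("abcde"))
        ns = normalize_synergies(s)
        assert np.allclose(ns.w, w)


def test_reconstruction_error_competitive_with_reference_solver(rng):
    """Independent cross-check: best-of-restarts error is as good as an
    established NMF implementation's on the same matrix and order."""
    from sklearn.decomposition import NMF as SkNMF

    m = rng.random((12, 60))
    ours = nmf_decompose(m, 3, n_restarts=30, max_iter=500, tol=1e-9, seed=0)
    ref = SkNMF(n_components=3, init="random", max_iter=2000, random_state=0, tol=1e-9)
    w_ref = ref.fit_transform(m)
    err_ref = np.linalg.norm(m - w_ref @ ref.components_)
    assert ours.objective <= err_ref * 1.02


def test_best_of_restarts_vaf_nondecreasing_in_k(rng):
    m = rng.random((10, 60))
    vafs = []
    for k in range(1, 6):
        s = nmf_decompose(m, k, n_restarts=50, seed=0)
        vafs.append(global_vaf(m, reconstruct(s)))
    assert np.all(np.diff(vafs) >= -1e-6)
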