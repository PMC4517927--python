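"""Incremental NMF memory: updates, decoding, learning dynamics."""

import numpy as np
import pytest

from hacnmf.hac import HACMVector
from hacnmf.memory import (
    decode,
    init_memory,
    kl_divergence,
    learn_utterance,
)

TINY = 1e-300


def sparse_vec(dense, acoustic_dim, keyword=None):
    dense = np.asarray(dense, dtype=np.float64)
    idx = np.nonzero(dense)[0]
    return HACMVector(
        dimension=len(dense),
        indices=idx,
        counts=dense[idx],
        acoustic_dim=acoustic_dim,
        keyword=keyword,
    )


def dense_reference_update(W, x, eta, inner_iters):
    """Independent dense implementation of one learning step.

    Multiplicative KL updates of h from uniform, then the per-primitive
    damped blend of the one-step multiplicative W update, then column
    renormalisation.
    """
    D, R = W.shape
    h = np.full(R, 1.0 / R)
    for _ in range(inner_iters):
        Wh = np.maximum(W @ h, TINY)
        h = np.maximum(h * (W.T @ (x / Wh)) / W.sum(axis=0), TINY)
    Wh = np.maximum(W @ h, TINY)
    Wstar = W * (x / Wh)[:, None]
    eta_j = eta * h / h.max()
    Wn = (1.0 - eta_j)[None, :] * W + eta_j[None, :] * Wstar
    return Wn / Wn.sum(axis=0)


class TestInitMemory:
    def test_default_geometry_is_110015_by_70(self):
        W = init_memory(70, seed=0)
        assert W.W.shape == (110_015, 70)

    def test_strictly_positive_and_column_normalised(self):
        W = init_memory(5, seed=1, acoustic_dim=50, meaning_dim=3)
        assert W.W.min() > 0
        assert np.allclose(W.W.sum(axis=0), 1.0, atol=1e-12)

    def test_deterministic(self):
        a = init_memory(4, seed=9, acoustic_dim=30, meaning_dim=3)
        b = init_memory(4, seed=9, acoustic_dim=30, meaning_dim=3)
        assert np.array_equal(a.W, b.W)

    def test_rejects_no_primitives(self):
        with pytest.raises(ValueError):
            init_memory(0, seed=1)


class TestLearnUtterance:
    def test_zero_step_leaves_memory_unchanged(self, rng):
        W = init_memory(4, seed=2, acoustic_dim=40, meaning_dim=3)
        before = W.W.copy()
        x = sparse_vec(rng.random(43) * (rng.random(43) < 0.3), 40)
        learn_utterance(W, x, eta=0.0)
        assert np.array_equal(W.W, before)

    def test_factored_update_matches_dense_reference(self, rng):
        D_a, D_m, R = 60, 3, 6
        W = init_memory(R, seed=3, acoustic_dim=D_a, meaning_dim=D_m)
        W_ref = W.W.copy()
        for t in range(40):
            dense = np.zeros(D_a + D_m)
            sup = rng.choice(D_a, 12, replace=False)
            dense[sup] = rng.random(12) * 10
            dense[D_a + t % D_m] = 5.0
            x = sparse_vec(dense, D_a)
            learn_utterance(W, x, eta=0.3, inner_iters=10)
            W_ref = dense_reference_update(W_ref, dense, eta=0.3, inner_iters=10)
        assert np.allclose(W.W, W_ref, rtol=1e-8, atol=1e-12)
        assert np.allclose(W.acoustic_colsums, W_ref[:D_a].sum(axis=0), rtol=1e-8)

    def test_nonnegativity_and_normalisation_preserved(self, rng):
        W = init_memory(5, seed=4, acoustic_dim=80, meaning_dim=3)
        for _ in range(30):
            dense = np.zeros(83)
            sup = rng.choice(80, 10, replace=False)
            dense[sup] = rng.random(10)
            learn_utterance(W, sparse_vec(dense, 80), eta=0.4)
            assert W.W.min() >= 0
            W.check_column_normalisation()

    def test_reconstruction_of_memorised_pattern_improves(self, rng):
        # x proportional to one primitive's own column: learning must not
        # increase the reconstruction divergence
        W = init_memory(4, seed=5, acoustic_dim=50, meaning_dim=2)
        col = W.W[:, 2] * 100.0
        x = sparse_vec(col, 50)

        def div(mem):
            h = np.full(4, 25.0)
            return kl_divergence(col, mem.W, h)

        before = div(W)
        learn_utterance(W, x, eta=0.2)
        assert div(W) <= before + 1e-12

    def test_repeated_presentation_monotonically_reduces_divergence(self, rng):
        D_a, R = 200, 6
        W = init_memory(R, seed=6, acoustic_dim=D_a, meaning_dim=2)
        dense = np.zeros(D_a + 2)
        sup = rng.choice(D_a, 30, replace=False)
        dense[sup] = rng.random(30) * 5
        x = sparse_vec(dense, D_a)
        divs = []
        for _ in range(100):
            learn_utterance(W, x, eta=0.05, inner_iters=25)
            Wsub = W.rows(x.indices)
            h = np.full(R, 1.0 / R)
            for _ in range(50):
                Wh = np.maximum(Wsub @ h, TINY)
                h = h * (Wsub.T @ (x.counts / Wh))
            divs.append(kl_divergence(dense, W.W, h))
        diffs = np.diff(divs)
        assert np.all(diffs <= 1e-8)

    def test_dimension_mismatch_rejected(self, rng):
        W = init_memory(3, seed=7, acoustic_dim=20, meaning_dim=2)
        with pytest.raises(ValueError):
            learn_utterance(W, sparse_vec(np.ones(10), 10))


class TestDecode:
    def test_orthogonal_supports_concentrate_weights(self):
        # primitives with disjoint acoustic support; v equals primitive 2
        D_a, R = 40, 4
        V = np.full((D_a + 2, R), 1e-9)
        for j in range(R):
            V[j * 10 : (j + 1) * 10, j] = 1.0
            V[D_a + j % 2, j] = 0.5
        from hacnmf.memory import MemoryMatrix

        W = MemoryMatrix(V, acoustic_dim=D_a, meaning_dim=2, seed=0)
        v = sparse_vec(np.concatenate([W.W_acoustic[:, 2] * 50, np.zeros(2)]), D_a)
        weights, act = decode(W, v, iters=100)
        assert weights.h[2] / weights.h.sum() >= 0.99
        assert np.isclose(act.a.sum(), 1.0)

    def test_activations_sum_to_one_and_deterministic(self, rng):
        W = init_memory(5, seed=8, acoustic_dim=60, meaning_dim=4)
        dense = np.zeros(64)
        dense[rng.choice(60, 8, replace=False)] = rng.random(8)
        v = sparse_vec(dense, 60)
        _, a1 = decode(W, v)
        _, a2 = decode(W, v)
        assert np.isclose(a1.a.sum(), 1.0)
        assert np.array_equal(a1.a, a2.a)

    def test_nonzero_meaning_block_rejected(self, rng):
        W = init_memory(5, seed=8, acoustic_dim=60, meaning_dim=4)
        dense = np.zeros(64)
        dense[61] = 1.0
        with pytest.raises(ValueError):
            decode(W, sparse_vec(dense, 60))

    def test_all_zero_vector_rejected(self):
        W = init_memory(5, seed=8, acoustic_dim=60, meaning_dim=4)
        with pytest.raises(ValueError):
            decode(W, sparse_vec(np.zeros(60), 60))


class TestSupervisionEndToEnd:
    def test_separable_patterns_decode_to_correct_keyword(self, rng):
        """Three keywords with distinct sparse acoustic signatures: after one
        pass of supervised learning, decoding held-out patterns must assign
        the highest activation to the correct keyword >= 95% of the time."""
        D_a, K, R = 90, 3, 9
        protos = np.zeros((K, D_a))
        for k in range(K):
            protos[k, k * 30 : (k + 1) * 30] = rng.random(30)

        def draw(k):
            dense = np.zeros(D_a + K)
            mask = rng.random(D_a) < 0.6
            dense[:D_a] = protos[k] * mask
            dense[:D_a] += 0.02 * rng.random(D_a)
            dense[:D_a] *= 100.0 / dense[:D_a].sum()
            return dense

        W = init_memory(R, seed=10, acoustic_dim=D_a, meaning_dim=K)
        for t in range(240):
            k = t % K
            dense = draw(k)
            dense[D_a + k] = 10.0
            learn_utterance(W, sparse_vec(dense, D_a), eta=0.4)
        correct = 0
        n_test = 60
        for t in range(n_test):
            k = t % K
            dense = draw(k)
            _, act = decode(W, sparse_vec(dense, D_a))
            correct += int(np.argmax(act.a) == k)
        assert correct / n_test >= 0.95

    def test_preference_sign_robust_to_activation_normalisation(self, rng):
        """Target-vs-foil preference must keep its sign whether or not
        per-sentence activations are normalised to sum one."""
        D_a, K, R = 90, 3, 9
        protos = np.zeros((K, D_a))
        for k in range(K):
            protos[k, k * 30 : (k + 1) * 30] = rng.random(30)
        W = init_memory(R, seed=12, acoustic_dim=D_a, meaning_dim=K)
        for t in range(240):
            k = t % K
            dense = np.zeros(D_a + K)
            dense[:D_a] = protos[k] * (rng.random(D_a) < 0.6) + 0.02
            dense[:D_a] *= 100.0 / dense[:D_a].sum()
            dense[D_a + k] = 10.0
            learn_utterance(W, sparse_vec(dense, D_a), eta=0.4)

        def scores(k_true):
            dense = np.zeros(D_a + K)
            dense[:D_a] = protos[k_true] * (rng.random(D_a) < 0.6) + 0.02
            dense[:D_a] *= 100.0 / dense[:D_a].sum()
            w, act = decode(W, sparse_vec(dense, D_a))
            raw = W.W_meaning @ w.h
            return act.a[0], raw[0]  # activation of keyword 0, both scalings

        t_norm = np.mean([scores(0)[0] for _ in range(10)])
        f_norm = np.mean([scores(1)[0] for _ in range(10)])
        t_raw = np.mean([scores(0)[1] for _ in range(10)])
        f_raw = np.mean([scores(1)[1] for _ in range(10)])
        assert np.sign(t_norm - f_norm) == np.sign(t_raw - f_raw) == 1.0
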