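import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import adjusted_rand_score

from phenoclust.baselines import kmeans_cluster
from phenoclust.dec import (AutoencoderSpec, init_centroids, kl_loss,
                            pretrain_autoencoder, run_dec_ensemble, soft_assign,
                            target_distribution, train_dec)

FAST = AutoencoderSpec(pretrain_epochs=40, learning_rate=0.05, seed=0)


def _random_Q(rng, n, k):
    Q = rng.uniform(0.01, 1.0, size=(n, k))
    return Q / Q.sum(axis=1, keepdims=True)


class TestPretrain:
    def test_linear_subspace_recovered(self):
        rng = np.random.default_rng(0)
        Z = rng.normal(size=(200, 3))
        W = rng.normal(size=(3, 8))
        X = Z @ W  # exactly rank 3, d_z = 4 suffices
        spec = AutoencoderSpec(layer_widths=(6, 4), activation="linear",
                               pretrain_epochs=400, learning_rate=0.05, seed=0)
        ae = pretrain_autoencoder(X, spec)
        assert ae.loss_trace[-1] < 1e-3

    def test_same_seed_identical_trace(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(80, 6))
        spec = AutoencoderSpec(pretrain_epochs=10, seed=5)
        a = pretrain_autoencoder(X, spec)
        b = pretrain_autoencoder(X, spec)
        assert a.loss_trace == b.loss_trace

    def test_beats_constant_predictor(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(150, 10))
        X[:, 0] = X[:, 1] + 0.1 * rng.normal(size=150)  # some structure to learn
        spec = AutoencoderSpec(pretrain_epochs=100, learning_rate=0.05, seed=0)
        ae = pretrain_autoencoder(X, spec)
        constant_mse = float(np.mean((X - X.mean(axis=0)) ** 2))
        final_mse = float(np.mean((ae.reconstruct(X) - X) ** 2))
        assert final_mse < constant_mse

    def test_loss_decreases(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(100, 5))
        ae = pretrain_autoencoder(X, AutoencoderSpec(pretrain_epochs=30, seed=1))
        assert ae.loss_trace[-1] < ae.loss_trace[0]

    def test_nonfinite_inputs_rejected(self):
        X = np.full((10, 3), np.nan)
        with pytest.raises(ValueError):
            pretrain_autoencoder(X, AutoencoderSpec(pretrain_epochs=1))


class TestInitCentroids:
    def test_point_masses_recovered(self):
        Z = np.repeat(np.array([[0.0, 0.0], [5.0, 5.0], [-3.0, 4.0]]), 10, axis=0)
        mu = init_centroids(Z, k=3, seed=0)
        expect = {(0.0, 0.0), (5.0, 5.0), (-3.0, 4.0)}
        got = {tuple(np.round(c, 9)) for c in mu}
        assert got == expect

    def test_deterministic(self):
        rng = np.random.default_rng(4)
        Z = rng.normal(size=(40, 3))
        np.testing.assert_array_equal(init_centroids(Z, 4, seed=3),
                                      init_centroids(Z, 4, seed=3))

    def test_matches_direct_kmeans(self):
        rng = np.random.default_rng(5)
        Z = rng.normal(size=(60, 4))
        mu = init_centroids(Z, 3, seed=9)
        direct = kmeans_cluster(Z, 3, seed=9).diagnostics["centers"]
        np.testing.assert_allclose(mu, direct)

    def test_n_smaller_than_k_rejected(self):
        with pytest.raises(ValueError):
            init_centroids(np.zeros((2, 2)), k=3)


class TestSoftAssign:
    def test_single_centroid_all_ones(self):
        rng = np.random.default_rng(6)
        Q = soft_assign(rng.normal(size=(10, 3)), np.zeros((1, 3)))
        np.testing.assert_allclose(Q, 1.0)

    def test_equidistant_point_symmetric(self):
        Q = soft_assign(np.array([[0.0, 0.0]]),
                        np.array([[1.0, 0.0], [-1.0, 0.0]]))
        np.testing.assert_allclose(Q, [[0.5, 0.5]])

    def test_kernel_evaluation(self):
        # alpha=1, squared distances (0, 1) -> weights (1, 0.5) -> (2/3, 1/3)
        Q = soft_assign(np.array([[0.0, 0.0]]),
                        np.array([[0.0, 0.0], [1.0, 0.0]]), alpha=1.0)
        np.testing.assert_allclose(Q, [[2.0 / 3.0, 1.0 / 3.0]], atol=1e-12)

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(7)
        Q = soft_assign(rng.normal(size=(30, 4)), rng.normal(size=(5, 4)))
        np.testing.assert_allclose(Q.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(Q > 0)


class TestTargetDistribution:
    def test_one_hot_fixed_point(self):
        Q = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 0.0]])
        np.testing.assert_allclose(target_distribution(Q), Q)

    def test_uniform_stays_uniform(self):
        Q = np.full((4, 3), 1.0 / 3.0)
        np.testing.assert_allclose(target_distribution(Q), Q, atol=1e-12)

    def test_hand_formula(self):
        Q = np.array([[0.8, 0.2], [0.6, 0.4]])
        f = Q.sum(axis=0)  # (1.4, 0.6)
        w = Q**2 / f
        expect = w / w.sum(axis=1, keepdims=True)
        np.testing.assert_allclose(target_distribution(Q), expect, atol=1e-12)
        assert f.tolist() == [pytest.approx(1.4), pytest.approx(0.6)]

    @settings(max_examples=50, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_sharpening_property(self, seed):
        # frequency normalization can de-sharpen rows whose argmax cluster is
        # over-represented, so the guarantee is asserted where it provably
        # holds: rows assigned to a minimum-frequency cluster, and any Q with
        # balanced cluster frequencies (where p ~ q^2 sharpens every row).
        rng = np.random.default_rng(seed)
        Q = _random_Q(rng, rng.integers(2, 20), rng.integers(2, 6))
        P = target_distribution(Q)
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-8)
        f = Q.sum(axis=0)
        min_freq_rows = np.isclose(f[np.argmax(Q, axis=1)], f.min())
        assert np.all(P.max(axis=1)[min_freq_rows]
                      >= Q.max(axis=1)[min_freq_rows] - 1e-12)

    def test_sharpening_balanced_frequencies(self):
        from itertools import permutations

        rng = np.random.default_rng(0)
        for _ in range(20):
            Q = _random_Q(rng, 10, 3)
            # stacking all column permutations equalizes cluster frequencies
            Qb = np.vstack([Q[:, list(p)] for p in permutations(range(3))])
            P = target_distribution(Qb)
            assert np.all(P.max(axis=1) >= Qb.max(axis=1) - 1e-12)


class TestKLLoss:
    def test_identical_zero(self):
        rng = np.random.default_rng(8)
        Q = _random_Q(rng, 5, 3)
        assert kl_loss(Q, Q) == pytest.approx(0.0, abs=1e-12)

    def test_closed_form(self):
        assert kl_loss(np.array([[1.0, 0.0]]), np.array([[0.5, 0.5]])) == \
            pytest.approx(np.log(2.0), abs=1e-12)

    def test_direct_summation_oracle(self):
        rng = np.random.default_rng(9)
        P, Q = _random_Q(rng, 8, 4), _random_Q(rng, 8, 4)
        expect = sum(
            P[i, j] * np.log(P[i, j] / Q[i, j])
            for i in range(8) for j in range(4)
        )
        assert kl_loss(P, Q) == pytest.approx(expect, abs=1e-12)

    @settings(max_examples=50, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_nonnegative_zero_iff_equal(self, seed):
        rng = np.random.default_rng(seed)
        P, Q = _random_Q(rng, 6, 3), _random_Q(rng, 6, 3)
        assert kl_loss(P, Q) >= 0.0
        if kl_loss(P, Q) < 1e-15:
            np.testing.assert_allclose(P, Q, atol=1e-6)

    def test_zero_q_rejected(self):
        with pytest.raises(ValueError):
            kl_loss(np.array([[1.0, 0.0]]), np.array([[0.0, 1.0]]))


class TestGradient:
    def test_dec_gradient_matches_finite_differences(self):
        """The analytic KL gradients w.r.t. z and centroids are correct."""
        rng = np.random.default_rng(10)
        n, k, d = 5, 3, 2
        Z = rng.normal(size=(n, d))
        mu = rng.normal(size=(k, d))
        P = _random_Q(rng, n, k)
        alpha = 1.0

        def loss(Zv, muv):
            return kl_loss(P, soft_assign(Zv, muv, alpha)) / n

        diff = Z[:, None, :] - mu[None, :, :]
        d2 = (diff**2).sum(axis=2)
        Q = soft_assign(Z, mu, alpha)
        coef = ((alpha + 1) / alpha) * (P - Q) / (1 + d2 / alpha) / n
        dz = (coef[:, :, None] * diff).sum(axis=1)
        dmu = -(coef[:, :, None] * diff).sum(axis=0)
        eps = 1e-6
        for i, j in [(0, 0), (2, 1), (4, 1)]:
            Zp, Zm = Z.copy(), Z.copy()
            Zp[i, j] += eps
            Zm[i, j] -= eps
            num = (loss(Zp, mu) - loss(Zm, mu)) / (2 * eps)
            assert dz[i, j] == pytest.approx(num, abs=1e-6)
        for i, j in [(0, 0), (1, 1), (2, 0)]:
            mup, mum = mu.copy(), mu.copy()
            mup[i, j] += eps
            mum[i, j] -= eps
            num = (loss(Z, mup) - loss(Z, mum)) / (2 * eps)
            assert dmu[i, j] == pytest.approx(num, abs=1e-6)


class TestTrainDEC:
    def test_recovers_separable_clusters(self, separable_features, separable_truth):
        wins = 0
        for seed in range(3):
            spec = AutoencoderSpec(pretrain_epochs=40, learning_rate=0.05, seed=seed)
            _, res, _ = train_dec(separable_features, 6, spec=spec,
                                  max_iter=800, update_interval=80)
            if adjusted_rand_score(separable_truth, res.labels) >= 0.8:
                wins += 1
        assert wins >= 2

    def test_tol_one_stops_at_first_update(self, separable_features):
        _, res, trace = train_dec(separable_features, 4, spec=FAST,
                                  max_iter=500, tol=1.0, update_interval=50)
        assert trace[-1].iteration == 50

    def test_trace_rows_and_loss_finite(self, separable_features):
        _, res, trace = train_dec(separable_features, 3, spec=FAST,
                                  max_iter=200, update_interval=50)
        assert all(np.isfinite(t.kl_loss) for t in trace)
        assert all(0.0 <= t.label_change_fraction <= 1.0 for t in trace)

    def test_k_below_two_rejected(self, separable_features):
        with pytest.raises(ValueError):
            train_dec(separable_features, 1, spec=FAST)


class TestEnsemble:
    def test_singleton_equals_train_dec(self, separable_features):
        ens = run_dec_ensemble(separable_features, 4, n_runs=1, base_seed=3,
                               spec=FAST, max_iter=300, update_interval=60)
        spec = AutoencoderSpec(pretrain_epochs=40, learning_rate=0.05, seed=3)
        _, direct, _ = train_dec(separable_features, 4, spec=spec,
                                 max_iter=300, update_interval=60)
        np.testing.assert_array_equal(ens[0][1].labels, direct.labels)

    def test_reproducible_per_seed(self, separable_features):
        a = run_dec_ensemble(separable_features, 3, n_runs=2, base_seed=0,
                             spec=FAST, max_iter=200, update_interval=50)
        b = run_dec_ensemble(separable_features, 3, n_runs=2, base_seed=0,
                             spec=FAST, max_iter=200, update_interval=50)
        for (_, ra), (_, rb) in zip(a, b):
            np.testing.assert_array_equal(ra.labels, rb.labels)

    def test_runs_agree_on_separable_data(self, separable_features):
        strong = AutoencoderSpec(pretrain_epochs=60, learning_rate=0.05, seed=0)
        ens = run_dec_ensemble(separable_features, 6, n_runs=4, base_seed=0,
                               spec=strong, max_iter=2000, update_interval=100)
        labels = [r.labels for _, r in ens]
        agree = sum(
            adjusted_rand_score(labels[i], labels[j]) >= 0.8
            for i in range(4) for j in range(i + 1, 4)
        )
        assert agree >= 5  # >= 5 of 6 pairs
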