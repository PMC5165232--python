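"""Gaussian-activation network: forward pass, gradients, hybrid training."""

import math

import numpy as np
import pytest

from lungtex.gaussian_net import (Deltas, NetworkParams, TrainingConfig,
                                  backprop_step, decode_params, encode_params,
                                  forward, gene_length, gradients, load_params,
                                  mse, predict, save_params, train_hybrid)
from lungtex.rcga import RCGAConfig

from oracles import mse_loops


def one_one_one(v=1.0, v0=0.0, w=1.0, w0=0.0, spread=1.0):
    return NetworkParams(np.array([[v]]), np.array([v0]),
                         np.array([[w]]), np.array([w0]), spread)


class TestForward:
    def test_zero_parameters_give_unit_activations(self):
        p = NetworkParams(np.zeros((4, 3)), np.zeros(3), np.zeros((3, 2)),
                          np.zeros(2), spread=3.0)
        z, y = forward(p, np.zeros(4))
        assert np.all(z == 1.0) and np.all(y == 1.0)

    def test_hand_evaluated_single_chain(self):
        # x=0: z_in=0, Z=1; y_in=1, Y=e^{-1}
        z, y = forward(one_one_one(), [0.0])
        assert z[0] == 1.0
        assert y[0] == pytest.approx(math.exp(-1.0), abs=1e-12)

    def test_large_spread_saturates_activations_to_one(self, rng):
        p = NetworkParams.random(5, 3, 2, spread=1e6, rng=rng)
        _, y = forward(p, rng.uniform(-1, 1, 5))
        assert np.all(y > 0.999999)

    def test_outputs_in_unit_interval(self, rng):
        p = NetworkParams.random(6, 3, 4, rng=rng)
        _, y = forward(p, rng.uniform(-2, 2, (20, 6)))
        assert np.all((y > 0) & (y <= 1))

    def test_shape_mismatch_rejected(self, rng):
        p = NetworkParams.random(6, 3, 4, rng=rng)
        with pytest.raises(ValueError, match="features"):
            forward(p, np.zeros(5))


class TestGradients:
    def test_matches_central_finite_differences(self, rng):
        for _ in range(5):
            p = NetworkParams.random(3, 2, 2, spread=3.0, rng=rng)
            x = rng.uniform(-1, 1, 3)
            t = np.array([1.0, 0.0])
            grad, _ = gradients(p, x, t)
            analytic = np.concatenate([grad.dv.ravel(), grad.dv0,
                                       grad.dw.ravel(), grad.dw0])
            genes = encode_params(p)
            h = 1e-6

            def loss(gv):
                pp = decode_params(gv, 3, 2, 2, 3.0)
                _, y = forward(pp, x)
                return 0.5 * float(((t - y) ** 2).sum())

            fd = np.empty_like(genes)
            for i in range(genes.size):
                up, down = genes.copy(), genes.copy()
                up[i] += h
                down[i] -= h
                fd[i] = (loss(up) - loss(down)) / (2 * h)
            # 1e-6 floor keeps finite-difference roundoff out of the ratio
            denom = np.maximum(np.abs(fd), 1e-6)
            assert np.max(np.abs(analytic - fd) / denom) < 1e-4

    def test_perfect_outputs_give_zero_update(self):
        p = one_one_one(spread=2.0)
        _, y = forward(p, [0.5])
        updated, deltas, _ = backprop_step(p, [[0.5]], [y], TrainingConfig(),
                                           Deltas.zeros(p))
        assert encode_params(updated) == pytest.approx(encode_params(p), abs=1e-15)
        assert np.all(deltas.dw == 0) and np.all(deltas.dv == 0)

    def test_hand_worked_single_step(self):
        # 1-1-1 net, sigma=1, alpha=0.5, no momentum, x=0.5, t=1
        v, v0, w, w0, s, alpha, x, t = 0.8, 0.1, 1.2, -0.2, 1.0, 0.5, 0.5, 1.0
        z_in = v0 + x * v
        z = math.exp(-z_in**2)
        y_in = w0 + z * w
        y = math.exp(-y_in**2)
        fprime = lambda a: -2 * a * math.exp(-a**2)
        delta_k = (t - y) * fprime(y_in)
        delta_j = delta_k * w * fprime(z_in)
        expected_w = w + alpha * delta_k * z
        expected_w0 = w0 + alpha * delta_k
        expected_v = v + alpha * delta_j * x
        expected_v0 = v0 + alpha * delta_j

        p = one_one_one(v, v0, w, w0, spread=s)
        cfg = TrainingConfig(learning_rate=alpha, momentum=0.0)
        updated, _, _ = backprop_step(p, [[x]], [[t]], cfg, Deltas.zeros(p))
        assert updated.hidden_output_weights[0, 0] == pytest.approx(expected_w, abs=1e-10)
        assert updated.output_biases[0] == pytest.approx(expected_w0, abs=1e-10)
        assert updated.input_hidden_weights[0, 0] == pytest.approx(expected_v, abs=1e-10)
        assert updated.hidden_biases[0] == pytest.approx(expected_v0, abs=1e-10)

    def test_small_step_does_not_increase_mse(self, rng):
        cfg = TrainingConfig(learning_rate=1e-3, momentum=0.0)
        for _ in range(20):
            p = NetworkParams.random(4, 3, 2, rng=rng)
            X = rng.uniform(0, 1, (1, 4))
            T = np.array([[1.0, 0.0]])
            before = mse(p, X, T)
            updated, _, after = backprop_step(p, X, T, cfg, Deltas.zeros(p))
            assert after <= before + 1e-8


class TestMse:
    def test_perfect_predictions_give_zero(self):
        p = NetworkParams(np.zeros((2, 2)), np.zeros(2), np.zeros((2, 3)),
                          np.zeros(3))
        X = np.zeros((4, 2))
        T = np.ones((4, 3))       # zero params force every output to 1
        assert mse(p, X, T) == 0.0

    def test_all_one_outputs_against_one_hot_target(self):
        p = NetworkParams(np.zeros((2, 2)), np.zeros(2), np.zeros((2, 5)),
                          np.zeros(5))
        T = np.eye(5)[[2]]
        assert mse(p, np.zeros((1, 2)), T) == pytest.approx(0.8)

    def test_agrees_with_loop_oracle(self, rng):
        p = NetworkParams.random(4, 3, 3, rng=rng)
        X = rng.uniform(0, 1, (10, 4))
        T = np.eye(3)[rng.integers(0, 3, 10)]
        _, y = forward(p, X)
        assert mse(p, X, T) == pytest.approx(mse_loops(T, y), abs=1e-12)

    def test_empty_dataset_rejected(self, rng):
        p = NetworkParams.random(2, 2, 2, rng=rng)
        with pytest.raises(ValueError, match="nonempty"):
            mse(p, np.empty((0, 2)), np.empty((0, 2)))


class TestEncoding:
    def test_round_trip_identity(self, rng):
        for _ in range(100):
            p = NetworkParams.random(4, 3, 2, rng=rng)
            q = decode_params(encode_params(p), 4, 3, 2, p.spread)
            assert np.array_equal(encode_params(p), encode_params(q))

    def test_standard_topology_gene_length(self):
        assert gene_length(12, 3, 5) == 59
        p = NetworkParams.random(12, 3, 5)
        assert encode_params(p).size == 59

    def test_zero_params_encode_to_zero_vector(self):
        p = NetworkParams(np.zeros((3, 2)), np.zeros(2), np.zeros((2, 2)),
                          np.zeros(2))
        assert not encode_params(p).any()

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError, match="length"):
            decode_params(np.zeros(10), 12, 3, 5)

    def test_json_round_trip(self, rng, tmp_path):
        p = NetworkParams.random(12, 3, 5, rng=rng)
        save_params(p, tmp_path / "model.json")
        q = load_params(tmp_path / "model.json")
        assert np.array_equal(encode_params(p), encode_params(q))
        assert q.spread == p.spread


class TestPredict:
    def test_argmax_class(self, rng):
        p = NetworkParams.random(3, 2, 5, rng=rng)
        _, scores = predict(p, rng.uniform(0, 1, (1, 3)))
        cls, _ = predict(p, rng.uniform(0, 1, (1, 3)))
        assert 0 <= cls[0] < 5

    def test_exact_tie_breaks_to_lowest_index(self):
        p = NetworkParams(np.zeros((2, 2)), np.zeros(2), np.zeros((2, 4)),
                          np.zeros(4))
        cls, scores = predict(p, np.zeros((1, 2)))
        assert np.all(scores == 1.0)
        assert cls[0] == 0


def two_cluster_data(seed, n_per=20, dim=12):
    rng = np.random.default_rng(seed)
    X = np.vstack([rng.normal(0.25, 0.05, (n_per, dim)),
                   rng.normal(0.75, 0.05, (n_per, dim))])
    y = np.repeat([0, 1], n_per)
    return X, np.eye(2)[y], y


class TestTrainHybrid:
    def test_infinite_target_returns_initial_params_untouched(self, rng):
        X, T, _ = two_cluster_data(0)
        cfg = TrainingConfig(target_mse=np.inf)
        params, history = train_hybrid(X, T, cfg, rng=rng)
        assert history.epochs == []

    def test_best_mse_sequence_non_increasing(self, rng):
        X, T, _ = two_cluster_data(1)
        _, history = train_hybrid(X, T, TrainingConfig(max_iterations=40),
                                  rng=rng)
        best = history.best_mses
        assert all(b <= a for a, b in zip(best, best[1:]))

    def test_separable_clusters_recovered(self):
        X, T, y = two_cluster_data(2)
        params, _ = train_hybrid(X, T, rng=np.random.default_rng(42))
        pred, _ = predict(params, X)
        assert (pred == y).mean() >= 0.95

    def test_seeded_training_is_bit_reproducible(self):
        X, T, _ = two_cluster_data(3)
        cfg = TrainingConfig(max_iterations=30)
        ga = RCGAConfig(generations=10)
        p1, h1 = train_hybrid(X, T, cfg, ga, np.random.default_rng(5))
        p2, h2 = train_hybrid(X, T, cfg, ga, np.random.default_rng(5))
        assert np.array_equal(encode_params(p1), encode_params(p2))
        assert h1.mses == h2.mses

    def test_ga_phase_never_worsens_best(self):
        X, T, _ = two_cluster_data(4)
        # stall_tol = 1 flags every epoch as stalled, so the GA must fire
        cfg = TrainingConfig(max_iterations=60, stall_patience=3,
                             stall_tol=1.0, target_mse=0.0)
        ga = RCGAConfig(generations=15)
        _, history = train_hybrid(X, T, cfg, ga, np.random.default_rng(7))
        best = history.best_mses
        assert all(b <= a for a, b in zip(best, best[1:]))
        assert "rcga" in history.phases     # the stall rule actually fired

    def test_empty_dataset_rejected(self, rng):
        with pytest.raises(ValueError, match="nonempty"):
            train_hybrid(np.empty((0, 12)), np.empty((0, 5)), rng=rng)
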