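"""Dense network: shapes, forward semantics, SGD training, gradient checks."""

import numpy as np
import pytest

from scbfl import (
    Cohort,
    ModelParams,
    TrainConfig,
    evaluate_scores,
    forward,
    init_model,
    load_model,
    save_model,
    train_local,
)
from scbfl.nn import _backward, cross_entropy


def zero_model(sizes):
    return ModelParams(
        weights=[np.zeros((sizes[l], sizes[l + 1])) for l in range(len(sizes) - 1)],
        biases=[np.zeros(sizes[l + 1]) for l in range(len(sizes) - 1)],
    )


class TestInitModel:
    def test_shapes_follow_layer_sizes(self):
        m = init_model((4, 3, 1), seed=0)
        assert m.weights[0].shape == (4, 3)
        assert m.weights[1].shape == (3, 1)
        assert [len(b) for b in m.biases] == [3, 1]
        assert m.layer_sizes == (4, 3, 1)

    def test_seeded_determinism(self):
        a, b = init_model((4, 3, 1), seed=5), init_model((4, 3, 1), seed=5)
        assert all(np.array_equal(x, y) for x, y in zip(a.weights, b.weights))

    def test_fan_in_scaling(self):
        m = init_model((1000, 64, 32, 1), seed=0)
        std = m.weights[0].std()
        assert abs(std - 1 / np.sqrt(1000)) < 0.2 / np.sqrt(1000)

    def test_rejects_degenerate_sizes(self):
        with pytest.raises(ValueError):
            init_model((4,), seed=0)
        with pytest.raises(ValueError):
            init_model((4, 0, 1), seed=0)


class TestForward:
    def test_zero_model_scores_one_half(self):
        m = zero_model((3, 2, 1))
        scores, hidden = forward(m, np.random.default_rng(0).random((5, 3)))
        assert np.allclose(scores, 0.5)
        assert len(hidden) == 1

    def test_dropout_is_noop_in_eval_mode(self, make_model):
        m = make_model((4, 3, 2, 1), seed=1)
        X = np.random.default_rng(1).random((6, 4))
        s0, _ = forward(m, X, mode="eval", dropout_rate=0.0)
        s9, _ = forward(m, X, mode="eval", dropout_rate=0.9)
        assert np.array_equal(s0, s9)

    def test_hand_computed_sigmoid(self):
        m = ModelParams(weights=[np.array([[1.0], [1.0]])], biases=[np.zeros(1)])
        scores, _ = forward(m, np.array([[1.0, 1.0]]))
        assert scores[0] == pytest.approx(1 / (1 + np.exp(-2)), abs=1e-10)

    def test_dropout_conservation(self, make_model):
        # inverted dropout is mean-preserving on the dropped layer's output
        m = make_model((5, 4, 3, 1), seed=2)
        X = np.abs(np.random.default_rng(2).random((8, 5))) + 0.5
        _, hidden_eval = forward(m, X, mode="eval")
        target = hidden_eval[-1]
        acc = np.zeros_like(target)
        n_draws = 10_000
        for s in range(n_draws):
            _, hidden = forward(m, X, mode="train", dropout_rate=0.4, seed=s)
            acc += hidden[-1]
        mean = acc / n_draws
        scale = np.abs(target).mean()
        assert np.abs(mean - target).max() < 0.02 * max(scale, 1.0) + 0.02

    def test_dimension_mismatch_raises(self, make_model):
        with pytest.raises(ValueError):
            forward(make_model((4, 3, 1)), np.zeros((2, 5)))


class TestGradients:
    def test_backprop_matches_central_finite_differences(self):
        """Every parameter of a 3-3-1 network, relative error < 1e-4.

        Continuous inputs keep every pre-activation away from the ReLU
        kink, where finite differences and the subgradient disagree."""
        m = init_model((3, 3, 1), seed=3)
        rng = np.random.default_rng(3)
        X = rng.normal(size=(20, 3))
        y = (rng.random(20) < 0.5).astype(float)
        dW, db, _ = _backward(m, X, y, None, 1.0)
        eps = 1e-6

        def loss_at(model):
            s, _ = forward(model, X)
            return cross_entropy(s, y)

        for l in range(m.n_layers):
            for arr, grad in ((m.weights[l], dW[l]), (m.biases[l], db[l])):
                it = np.nditer(arr, flags=["multi_index"])
                for _ in it:
                    ix = it.multi_index
                    orig = arr[ix]
                    arr[ix] = orig + eps
                    up = loss_at(m)
                    arr[ix] = orig - eps
                    down = loss_at(m)
                    arr[ix] = orig
                    fd = (up - down) / (2 * eps)
                    denom = max(abs(fd), abs(grad[ix]), 1e-8)
                    assert abs(fd - grad[ix]) / denom < 1e-4

    def test_one_full_batch_step_equals_analytic_gradient(self, tiny_cohort):
        """epochs=1, batch=n, no dropout: delta = -lr * dLoss/dW (FD oracle)."""
        m = init_model((2, 2, 1), seed=4)
        cfg = TrainConfig(
            learning_rate=0.5, batch_size=4, epochs_per_loop=1, dropout_rate=0.0, seed=0
        )
        _, grad = train_local(m, tiny_cohort, cfg)
        X, y = tiny_cohort.features, tiny_cohort.labels
        eps = 1e-6
        for l in range(m.n_layers):
            it = np.nditer(m.weights[l], flags=["multi_index"])
            for _ in it:
                ix = it.multi_index
                orig = m.weights[l][ix]
                m.weights[l][ix] = orig + eps
                up = cross_entropy(forward(m, X)[0], y)
                m.weights[l][ix] = orig - eps
                down = cross_entropy(forward(m, X)[0], y)
                m.weights[l][ix] = orig
                fd = (up - down) / (2 * eps)
                assert grad.deltas[l][ix] == pytest.approx(-0.5 * fd, abs=1e-5)


class TestTrainLocal:
    def test_zero_learning_rate_changes_nothing(self, small_cohort, make_model):
        m = make_model((12, 4, 1))
        updated, grad = train_local(m, small_cohort, TrainConfig(learning_rate=0.0))
        assert all(np.array_equal(a, b) for a, b in zip(updated.weights, m.weights))
        assert all(np.all(d == 0) for d in grad.deltas)

    def test_input_model_is_not_mutated(self, small_cohort, make_model):
        m = make_model((12, 4, 1))
        before = [W.copy() for W in m.weights]
        train_local(m, small_cohort, TrainConfig(seed=1))
        assert all(np.array_equal(a, b) for a, b in zip(m.weights, before))

    def test_seeded_training_is_deterministic(self, small_cohort, make_model):
        m = make_model((12, 4, 1))
        u1, _ = train_local(m, small_cohort, TrainConfig(seed=3))
        u2, _ = train_local(m, small_cohort, TrainConfig(seed=3))
        assert all(np.array_equal(a, b) for a, b in zip(u1.weights, u2.weights))
        assert all(np.array_equal(a, b) for a, b in zip(u1.biases, u2.biases))

    @pytest.mark.parametrize("seed", range(5))
    def test_loss_decreases_after_five_epochs(self, seed):
        from scbfl import generate_cohort

        c = generate_cohort(400, 20, 10, base_log_odds=0.0, effect_scale=2.0, seed=seed)
        m = init_model((20, 8, 1), seed=seed)
        before = cross_entropy(evaluate_scores(m, c), c.labels)
        updated, _ = train_local(m, c, TrainConfig(seed=seed))
        after = cross_entropy(evaluate_scores(updated, c), c.labels)
        assert after < before

    def test_empty_shard_rejected(self, make_model):
        with pytest.raises(ValueError):
            Cohort(features=np.empty((0, 2)), labels=np.empty(0))


class TestEvaluateScores:
    def test_row_permutation_permutes_scores(self, small_cohort, make_model):
        m = make_model((12, 4, 1), seed=6)
        perm = np.random.default_rng(0).permutation(small_cohort.n_samples)
        s = evaluate_scores(m, small_cohort)
        s_perm = evaluate_scores(m, small_cohort.subset(perm))
        assert np.allclose(s[perm], s_perm)

    def test_matches_eval_forward_bitwise(self, small_cohort, make_model):
        m = make_model((12, 4, 1), seed=6)
        assert np.array_equal(
            evaluate_scores(m, small_cohort), forward(m, small_cohort.features)[0]
        )


def test_model_serialization_round_trip(tmp_path, make_model):
    m = make_model((5, 3, 1), seed=8)
    save_model(m, tmp_path / "m.json")
    back = load_model(tmp_path / "m.json")
    assert back.layer_sizes == m.layer_sizes
    assert all(np.array_equal(a, b) for a, b in zip(back.weights, m.weights))
    assert all(np.array_equal(a, b) for a, b in zip(back.biases, m.biases))
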