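"""Attention/merge operator correctness against literal brute-force oracles,
autodiff gradient checks, and basic-learner training contracts."""

import numpy as np
import pytest

from ppistack.autograd import Tensor, conv1d_same, softmax_cross_entropy
from ppistack.neural import (
    AttentionConfig,
    BasicLearner,
    ConvConfig,
    LearnerConfig,
    conv_stack,
    merge_pair,
    multi_head,
    pooled_multi_head,
    scaled_dot_attention,
    train_basic,
)

from oracles import (
    attention_oracle,
    merge_oracle,
    multi_head_oracle,
    pooled_oracle,
    softmax_rows,
)


def _rand_mats(rng, P=5, d=4):
    Q, K, V = (rng.normal(size=(P, d)) for _ in range(3))
    Wq, Wk, Wv, Wmu = (rng.normal(size=(d, d)) for _ in range(4))
    return Q, K, V, Wq, Wk, Wv, Wmu


# ---------------------------------------------------------------------------
# scaled dot-product attention


class TestScaledDotAttention:
    def test_weights_are_row_stochastic(self, rng):
        Q, K, V, *_ = _rand_mats(rng)
        w, _ = scaled_dot_attention(Q, K, V)
        assert np.allclose(w.data.sum(axis=-1), 1.0)
        assert np.all(w.data >= 0)

    def test_two_by_two_hand_case(self):
        Q = np.array([[1.0, 0.0], [0.0, 1.0]])
        K = np.eye(2)
        V = np.array([[1.0, 2.0], [3.0, 4.0]])
        w, out = scaled_dot_attention(Q, K, V)
        s = 1 / np.sqrt(2)
        e = np.exp(np.array([[s, 0.0], [0.0, s]]))
        expected_w = e / e.sum(axis=1, keepdims=True)
        assert np.allclose(w.data, expected_w, atol=1e-12)
        assert np.allclose(out.data, expected_w @ V, atol=1e-12)

    def test_softmax_saturation_selects_aligned_key(self):
        K = np.eye(3) * 50
        V = np.array([[1.0, 0, 0], [0, 1.0, 0], [0, 0, 1.0]])
        Q = np.array([[0.0, 50.0, 0.0]])
        w, out = scaled_dot_attention(Q, K, V)
        assert w.data[0, 1] > 0.999
        assert np.allclose(out.data[0], V[1], atol=1e-3)

    def test_dimension_mismatch_raises(self, rng):
        with pytest.raises(ValueError, match="width"):
            scaled_dot_attention(rng.normal(size=(3, 4)),
                                 rng.normal(size=(3, 5)),
                                 rng.normal(size=(3, 5)))
        with pytest.raises(ValueError, match="rows"):
            scaled_dot_attention(rng.normal(size=(3, 4)),
                                 rng.normal(size=(6, 4)),
                                 rng.normal(size=(3, 4)))

    def test_matches_oracle_many_seeds(self):
        for seed in range(100):
            r = np.random.default_rng(seed)
            P, d = int(r.integers(2, 7)), int(r.integers(2, 6))
            Q, K, V = (r.normal(size=(P, d)) for _ in range(3))
            w, out = scaled_dot_attention(Q, K, V)
            ow, oo = attention_oracle(Q, K, V)
            np.testing.assert_allclose(w.data, ow, rtol=1e-9)
            np.testing.assert_allclose(out.data, oo, rtol=1e-9, atol=1e-12)


class TestMultiHead:
    def test_single_head_identity_projection_reduces_to_attention(self, rng):
        Q, K, V, *_ = _rand_mats(rng)
        eye = np.eye(4)
        out = multi_head(Q, K, V, eye, eye, eye, eye, h=1)
        _, expected = scaled_dot_attention(Q, K, V)
        assert np.allclose(out.data, expected.data, atol=1e-12)

    def test_output_rows_match_query_rows(self, rng):
        Q, K, V, Wq, Wk, Wv, Wmu = _rand_mats(rng, P=6)
        for h in (1, 2, 4):
            out = multi_head(Q[:3], K, V, Wq, Wk, Wv, Wmu, h=h)
            assert out.shape == (3, 4)

    def test_joint_permutation_of_keys_and_values_is_invariant(self, rng):
        Q, K, V, Wq, Wk, Wv, Wmu = _rand_mats(rng)
        perm = rng.permutation(K.shape[0])
        a = multi_head(Q, K, V, Wq, Wk, Wv, Wmu, h=2)
        b = multi_head(Q, K[perm], V[perm], Wq, Wk, Wv, Wmu, h=2)
        assert np.allclose(a.data, b.data, atol=1e-12)

    def test_indivisible_heads_raise(self, rng):
        Q, K, V, Wq, Wk, Wv, Wmu = _rand_mats(rng)
        with pytest.raises(ValueError, match="divisible"):
            multi_head(Q, K, V, Wq, Wk, Wv, Wmu, h=3)

    def test_matches_oracle_many_seeds(self):
        for seed in range(100):
            r = np.random.default_rng(1000 + seed)
            h = int(r.choice([1, 2, 4]))
            d = int(h * r.integers(1, 4))
            P = int(r.integers(2, 7))
            Q, K, V = (r.normal(size=(P, d)) for _ in range(3))
            Wq, Wk, Wv, Wmu = (r.normal(size=(d, d)) for _ in range(4))
            out = multi_head(Q, K, V, Wq, Wk, Wv, Wmu, h)
            expected = multi_head_oracle(Q, K, V, Wq, Wk, Wv, Wmu, h)
            np.testing.assert_allclose(out.data, expected, rtol=1e-9, atol=1e-12)


class TestPooledMultiHead:
    def test_output_length_independent_of_row_count(self, rng):
        _, _, _, Wq, Wk, Wv, Wmu = _rand_mats(rng)
        for P in (3, 8, 20):
            Q, K, V = (rng.normal(size=(P, 4)) for _ in range(3))
            out = pooled_multi_head(Q, K, V, Wq, Wk, Wv, Wmu, h=2)
            assert out.shape == (8,)  # 2 * d_model

    def test_constant_inputs_make_avg_equal_max(self):
        Q = np.ones((5, 4))
        eye = np.eye(4)
        out = pooled_multi_head(Q, Q, Q, eye, eye, eye, eye, h=1).data
        assert np.allclose(out[:4], out[4:], atol=1e-12)

    def test_matches_oracle_many_seeds(self):
        for seed in range(100):
            r = np.random.default_rng(2000 + seed)
            h = int(r.choice([1, 2]))
            d = int(h * r.integers(1, 4))
            P = int(r.integers(2, 7))
            Q, K, V = (r.normal(size=(P, d)) for _ in range(3))
            Wq, Wk, Wv, Wmu = (r.normal(size=(d, d)) for _ in range(4))
            out = pooled_multi_head(Q, K, V, Wq, Wk, Wv, Wmu, h)
            expected = pooled_oracle(Q, K, V, Wq, Wk, Wv, Wmu, h)
            np.testing.assert_allclose(out.data, expected, rtol=1e-9, atol=1e-12)


class TestMergePair:
    def test_self_merge_with_identity(self, rng):
        a = rng.normal(size=6)
        out = merge_pair(a, a, np.eye(6)).data
        assert np.isclose(out[0], 1.0, atol=1e-9)
        assert np.isclose(out[1], np.sum(a**2), atol=1e-9)

    def test_orthogonal_vectors(self):
        a = np.array([1.0, 0.0, 0.0])
        b = np.array([0.0, 2.0, 0.0])
        out = merge_pair(a, b, np.eye(3)).data
        assert np.isclose(out[0], 0.0, atol=1e-9)
        assert np.isclose(out[1], 0.0, atol=1e-9)

    def test_zero_norm_gives_zero_cosine(self):
        a = np.zeros(4)
        b = np.ones(4)
        out = merge_pair(a, b, np.eye(4)).data
        assert out[0] == 0.0

    def test_output_length_is_2d_plus_2(self, rng):
        for d in (3, 8):
            a, b = rng.normal(size=d), rng.normal(size=d)
            out = merge_pair(a, b, rng.normal(size=(d, d)))
            assert out.shape == (2 * d + 2,)

    def test_cosine_term_is_symmetric_under_pair_swap(self, rng):
        a, b = rng.normal(size=5), rng.normal(size=5)
        A = rng.normal(size=(5, 5))
        assert np.isclose(
            merge_pair(a, b, A).data[0], merge_pair(b, a, A).data[0], atol=1e-12
        )

    def test_matches_oracle_many_seeds(self):
        for seed in range(100):
            r = np.random.default_rng(3000 + seed)
            d = int(r.integers(2, 8))
            a, b = r.normal(size=d), r.normal(size=d)
            A = r.normal(size=(d, d))
            np.testing.assert_allclose(
                merge_pair(a, b, A).data, merge_oracle(a, b, A), rtol=1e-9,
                atol=1e-12,
            )


# ---------------------------------------------------------------------------
# convolution stack


class TestConvStack:
    def test_shape_preserved_under_same_padding(self, rng):
        x = rng.normal(size=(3, 10, 2))
        out = conv_stack(x, ConvConfig(positions=10, in_channels=2, channels=5))
        assert out.shape == (3, 10, 5)

    def test_zero_input_zero_output_with_zero_bias(self, rng):
        w = Tensor(rng.normal(size=(3, 2, 4)))
        b = Tensor(np.zeros(4))
        out = conv1d_same(Tensor(np.zeros((1, 6, 2))), w, b)
        assert np.allclose(out.data, 0.0)

    def test_hand_computed_convolution(self):
        # 6 positions, 1 channel in/out, kernel [1, 2, 3]: out[p] =
        # 1*x[p-1] + 2*x[p] + 3*x[p+1] with zero padding
        x = np.arange(6, dtype=float).reshape(1, 6, 1)
        w = np.array([1.0, 2.0, 3.0]).reshape(3, 1, 1)
        out = conv1d_same(Tensor(x), Tensor(w), Tensor(np.zeros(1))).data.ravel()
        expected = [2 * 0 + 3 * 1, 0 + 2 + 6, 1 + 4 + 9, 2 + 6 + 12,
                    3 + 8 + 15, 4 + 10 + 0]
        assert np.allclose(out, expected)

    def test_shape_mismatch_reports_expected_and_got(self, rng):
        cfg = ConvConfig(positions=10, in_channels=2)
        with pytest.raises(ValueError, match="expected"):
            conv_stack(rng.normal(size=(3, 9, 2)), cfg)


# ---------------------------------------------------------------------------
# autodiff gradient check on the full learner


def test_learner_gradients_match_finite_differences(rng):
    cfg = LearnerConfig(
        "pseaac",
        ConvConfig(positions=6, in_channels=1, channels=4),
        AttentionConfig(h=2, d_model=4),
        dense_layers=(5,),
        seed=1,
        dtype="float64",
        standardize=False,
    )
    learner = BasicLearner(cfg)
    X1 = rng.normal(size=(3, 6, 1))
    X2 = rng.normal(size=(3, 6, 1))
    y = np.array([0, 1, 1])

    def loss_value():
        return float(
            softmax_cross_entropy(learner.forward(X1, X2, train=True), y).data
        )

    for p in learner.params:
        p.grad = None
    loss = softmax_cross_entropy(learner.forward(X1, X2, train=True), y)
    loss.backward()

    checked = 0
    for p in learner.params:
        g = p.grad if p.grad is not None else np.zeros_like(p.data)
        flat = p.data.ravel()
        gflat = np.asarray(g).ravel()
        for ix in range(0, flat.size, max(1, flat.size // 3)):
            eps = 1e-6
            old = flat[ix]
            flat[ix] = old + eps
            lp = loss_value()
            flat[ix] = old - eps
            lm = loss_value()
            flat[ix] = old
            numeric = (lp - lm) / (2 * eps)
            # combined tolerance: ReLU/max-pool kinks and the BN-cancelled
            # conv-bias direction produce tiny absolute discrepancies
            assert abs(numeric - gflat[ix]) < 1e-6 + 1e-4 * (
                abs(numeric) + abs(gflat[ix])
            )
            checked += 1
    assert checked > 30


# ---------------------------------------------------------------------------
# training contracts


def _easy_pair_task(n=240, P=12, seed=0):
    """Pairs interact iff both carry a planted +2 block in the same channel."""
    r = np.random.default_rng(seed)
    X1 = r.normal(size=(n, P, 1))
    X2 = r.normal(size=(n, P, 1))
    y = r.integers(0, 2, size=n)
    for i in np.flatnonzero(y == 1):
        X1[i, 3:7, 0] += 2.0
        X2[i, 3:7, 0] += 2.0
    return X1, X2, y


def _tiny_cfg(seed=0, epochs=25):
    return LearnerConfig(
        "pseaac",
        ConvConfig(positions=12, in_channels=1, channels=6),
        AttentionConfig(h=2, d_model=6),
        dense_layers=(16,),
        seed=seed,
        epochs=epochs,
        batch_size=32,
    )


class TestTrainBasic:
    def test_learns_planted_signal(self):
        X1, X2, y = _easy_pair_task()
        learner = train_basic(X1[:180], X2[:180], y[:180], _tiny_cfg())
        preds = learner.predict_positive(X1[180:], X2[180:])
        acc = np.mean((preds >= 0.5) == y[180:])
        assert acc > 0.9

    def test_predict_proba_rows_sum_to_one(self):
        X1, X2, y = _easy_pair_task(n=40)
        learner = train_basic(X1, X2, y, _tiny_cfg(epochs=2))
        proba = learner.predict_proba(X1[:10], X2[:10])
        assert proba.shape == (10, 2)
        assert np.allclose(proba.sum(axis=1), 1.0, atol=1e-5)

    def test_training_is_deterministic_given_seed(self):
        X1, X2, y = _easy_pair_task(n=80)
        a = train_basic(X1, X2, y, _tiny_cfg(seed=5, epochs=4))
        b = train_basic(X1, X2, y, _tiny_cfg(seed=5, epochs=4))
        assert [h["train_loss"] for h in a.history] == [
            h["train_loss"] for h in b.history
        ]
        assert np.array_equal(
            a.predict_positive(X1[:8], X2[:8]), b.predict_positive(X1[:8], X2[:8])
        )

    def test_single_class_raises(self):
        X1, X2, _ = _easy_pair_task(n=20)
        with pytest.raises(ValueError, match="both classes"):
            train_basic(X1, X2, np.ones(20, dtype=int), _tiny_cfg())

    def test_state_roundtrip_preserves_predictions(self, tmp_path):
        X1, X2, y = _easy_pair_task(n=60)
        cfg = _tiny_cfg(epochs=3)
        learner = train_basic(X1, X2, y, cfg)
        fresh = BasicLearner(cfg)
        fresh.load_state_arrays(learner.state_arrays())
        assert np.array_equal(
            learner.predict_positive(X1[:9], X2[:9]),
            fresh.predict_positive(X1[:9], X2[:9]),
        )
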