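"""Loss, stratified splitting, gradient fidelity, and the training loop."""

import math

import numpy as np
import pytest

from lexcnn.model import (AttentionCNNParams, backward_batch, forward_batch,
                          init_params)
from lexcnn.preprocess import CATEGORIES
from lexcnn.synthetic import generate_corpus, generate_lexicon, planted_signal_spec
from lexcnn.training import (TrainConfig, TrainHistory, TrainingError,
                             loss, select_best_iteration, split_train_val,
                             train)


def small_spec(posts_per_category=50):
    spec = planted_signal_spec()
    spec.posts_per_category = posts_per_category
    spec.post_length_mean, spec.post_length_min, spec.post_length_max = 15, 6, 30
    return spec


def fast_config(**over):
    base = dict(d=8, windows=(2,), kernels_per_window=4, n=40,
                max_iterations=60, eval_every=20, k=3, batch_size=20,
                seed=0, variant="cnn_random", l2_lambda=0.0, dropout=0.0,
                learning_rate=0.01)
    base.update(over)
    return TrainConfig(**base)


class TestLoss:
    def test_uniform_prediction_cross_entropy(self):
        probs = np.full((3, 4), 0.25)
        y = np.eye(4)[[0, 1, 2]]
        assert loss(probs, y, None, 0.0) == pytest.approx(-math.log(0.25))
        assert loss(probs, y, None, 0.0) == pytest.approx(1.38629, abs=1e-5)

    def test_perfect_prediction_is_zero(self):
        y = np.eye(4)[[2, 3]]
        assert loss(y.copy(), y, None, 0.0) == pytest.approx(0.0, abs=1e-12)

    def test_l2_penalty_half_lambda_norm(self):
        """Unit-norm weight vector, lambda=0.1 -> penalty 0.05."""
        params = AttentionCNNParams(windows=(), V=np.array([[1.0, 0, 0, 0]]).T
                                    .reshape(4, 1) * 0.0, b_out=np.zeros(4))
        params.V[0, 0] = 1.0  # ||V||^2 = 1
        y = np.eye(4)[[0]]
        assert loss(y.copy(), y, params, 0.1) == pytest.approx(0.05)

    def test_zero_probability_clamped(self):
        probs = np.array([[0.0, 1.0, 0.0, 0.0]])
        y = np.eye(4)[[0]]
        val = loss(probs, y, None, 0.0)
        assert np.isfinite(val) and val == pytest.approx(-math.log(1e-12))

    def test_empty_batch_rejected(self):
        with pytest.raises(TrainingError):
            loss(np.zeros((0, 4)), np.zeros((0, 4)), None, 0.0)

    def test_penalty_monotone_in_weight_magnitude(self):
        params = init_params(3, (2,), 2, seed=0)
        y = np.eye(4)[[0]]
        base = loss(y.copy(), y, params, 0.1)
        params.kernels[2][0, 0, 0] += 1.0
        assert loss(y.copy(), y, params, 0.1) > base


class TestSplit:
    class P:
        def __init__(self, label, i):
            self.label, self.post_id = label, f"{label}{i}"

    def corpus(self, per_label):
        return [self.P(c, i) for c in CATEGORIES for i in range(per_label)]

    def test_ninety_ten_split_stratified(self):
        corpus = self.corpus(25)  # 100 posts
        tr, va = split_train_val(corpus, 0.9, seed=0)
        assert len(tr) == 90 and len(va) == 10
        from collections import Counter
        for c in CATEGORIES:
            assert abs(Counter(p.label for p in tr)[c] - 22.5) <= 1

    def test_seed_reproducible(self):
        corpus = self.corpus(10)
        a = split_train_val(corpus, 0.8, seed=3)
        b = split_train_val(corpus, 0.8, seed=3)
        assert [p.post_id for p in a[0]] == [p.post_id for p in b[0]]

    def test_half_split_of_eight(self):
        corpus = self.corpus(2)
        tr, va = split_train_val(corpus, 0.5, seed=1)
        from collections import Counter
        assert Counter(p.label for p in tr) == Counter(p.label for p in va)
        assert {p.post_id for p in tr} | {p.post_id for p in va} == \
            {p.post_id for p in corpus}

    def test_rare_label_raises_naming_it(self):
        corpus = self.corpus(3) + [self.P("crisis", 99)]
        corpus = [p for p in corpus if not (p.label == "green" and p.post_id != "green0")]
        with pytest.raises(TrainingError, match="green"):
            split_train_val(corpus, 0.7, seed=0)


class TestSelectBestIteration:
    def make(self, iters, vals):
        h = TrainHistory()
        for i, v in zip(iters, vals):
            h.record(i, 1.0, 0.5, v)
        return h

    def test_argmax(self):
        assert select_best_iteration(self.make([100, 200, 300], [0.5, 0.8, 0.7])) == 200

    def test_monotone_series_picks_last(self):
        assert select_best_iteration(self.make([1, 2, 3], [0.1, 0.2, 0.3])) == 3

    def test_tie_picks_earliest(self):
        assert select_best_iteration(self.make([200, 300, 400], [0.8, 0.7, 0.8])) == 200

    def test_empty_history_rejected(self):
        with pytest.raises(TrainingError):
            select_best_iteration(TrainHistory())


def flatten(params):
    parts = [params.V.ravel(), params.b_out.ravel()]
    for h in params.windows:
        parts += [params.kernels[h].ravel(), params.biases[h].ravel()]
    return np.concatenate(parts)


def unflatten(theta, params):
    out = init_params(params.kernels[params.windows[0]].shape[2],
                      params.windows, params.kernels[params.windows[0]].shape[0],
                      seed=0, dropout=0.0)
    i = 0
    for arr_name in ("V", "b_out"):
        arr = getattr(params, arr_name)
        setattr(out, arr_name, theta[i:i + arr.size].reshape(arr.shape).copy())
        i += arr.size
    for h in params.windows:
        k = params.kernels[h]
        out.kernels[h] = theta[i:i + k.size].reshape(k.shape).copy()
        i += k.size
        b = params.biases[h]
        out.biases[h] = theta[i:i + b.size].reshape(b.shape).copy()
        i += b.size
    return out


def test_analytic_gradient_matches_central_differences(rng):
    """Finite-difference oracle for the full backprop chain (<=20 params)."""
    d, h, m, n, B = 2, 2, 1, 4, 3
    params = init_params(d, (h,), m, seed=1, dropout=0.0)
    theta0 = flatten(params)
    assert theta0.size <= 20
    X = rng.normal(size=(B, n, d))
    a = rng.uniform(1.0, 1.6, size=(B, n))
    y = np.eye(4)[[0, 2, 3]]
    lam = 0.05

    def loss_of(theta):
        p = unflatten(theta, params)
        probs, _ = forward_batch(X, a, p)
        return loss(probs, y, p, lam)

    probs, cache = forward_batch(X, a, params)
    grads = backward_batch(cache, y, params, lam, train_embeddings=True)
    analytic = flatten(AttentionCNNParams(
        windows=params.windows, kernels=grads["kernels"], biases=grads["biases"],
        V=grads["V"], b_out=grads["b_out"]))

    eps = 1e-5
    fd = np.zeros_like(theta0)
    for i in range(theta0.size):
        tp, tm = theta0.copy(), theta0.copy()
        tp[i] += eps
        tm[i] -= eps
        fd[i] = (loss_of(tp) - loss_of(tm)) / (2 * eps)
    rel = np.abs(analytic - fd) / np.maximum(1e-8, np.abs(analytic) + np.abs(fd))
    assert rel.max() < 1e-4

    # embedding-path gradient dX against the same oracle on a few entries
    for (b, j, k) in [(0, 1, 0), (2, 3, 1), (1, 0, 1)]:
        Xp, Xm = X.copy(), X.copy()
        Xp[b, j, k] += eps
        Xm[b, j, k] -= eps
        pp, _ = forward_batch(Xp, a, params)
        pm, _ = forward_batch(Xm, a, params)
        fd_x = (loss(pp, y, params, lam) - loss(pm, y, params, lam)) / (2 * eps)
        g = grads["dX"][b, j, k]
        assert abs(g - fd_x) / max(1e-8, abs(g) + abs(fd_x)) < 1e-4


@pytest.fixture(scope="module")
def separable():
    spec = small_spec(50)
    lex = generate_lexicon(spec, 2)
    return generate_corpus(spec, lex, 2), lex


class TestTrainLoop:
    def test_loss_decreases_on_separable_data(self, separable):
        corpus, lex = separable
        cfg = fast_config(max_iterations=200, eval_every=10)
        _, hist = train(corpus, lex, cfg)
        i10 = hist.iterations.index(10)
        i200 = hist.iterations.index(200)
        assert hist.train_loss[i200] < hist.train_loss[i10]

    def test_descent_across_seeds(self, separable):
        """Full-train loss after 50 iterations below the 10-iteration value
        in >=95% of seeds (lambda = 0, dropout = 0)."""
        corpus, lex = separable
        wins = 0
        n_seeds = 30
        for seed in range(n_seeds):
            cfg = fast_config(max_iterations=50, eval_every=10, seed=seed)
            _, hist = train(corpus, lex, cfg)
            wins += hist.train_loss[-1] < hist.train_loss[0]
        assert wins >= math.ceil(0.95 * n_seeds)

    def test_seed_determinism_bit_identical(self, separable):
        corpus, lex = separable
        cfg = fast_config(max_iterations=30, eval_every=10, variant="liwc_cnn",
                          w2v_epochs=1)
        c1, h1 = train(corpus, lex, cfg)
        c2, h2 = train(corpus, lex, cfg)
        np.testing.assert_array_equal(c1.params.V, c2.params.V)
        for h in c1.params.windows:
            np.testing.assert_array_equal(c1.params.kernels[h], c2.params.kernels[h])
        np.testing.assert_array_equal(c1.emb.vectors, c2.emb.vectors)
        assert h1.val_acc == h2.val_acc

    def test_missing_lexicon_for_attention_variant(self, separable):
        corpus, _ = separable
        with pytest.raises(TrainingError):
            train(corpus, None, fast_config(variant="liwc_cnn"))

    def test_invalid_config_rejected(self):
        with pytest.raises(TrainingError):
            TrainConfig(variant="transformer").validate()
        with pytest.raises(TrainingError):
            TrainConfig(dropout=1.0).validate()
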