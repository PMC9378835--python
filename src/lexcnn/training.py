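"""Loss, optimization loop, stratified splitting and iteration selection.

The objective is mean categorical cross-entropy over the four triage
categories plus an L2 penalty (lambda/2)*||w||^2 on the convolution kernels
and dense weights (biases and embeddings are excluded).  Optimization is
mini-batch Adam; one *iteration* is one mini-batch step.  Validation accuracy
is recorded every ``eval_every`` iterations and the checkpoint at the
validation-accuracy peak (earliest on ties) is the one returned, mirroring
the pick-the-peak model-selection rule this method family uses.

Gradients are the analytic backprop of the model module; their fidelity is
guarded by a central-finite-difference oracle in the test suite.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.model_selection import StratifiedShuffleSplit

from lexcnn import model as model_mod
from lexcnn.embedding import (EmbeddingMatrix, build_vocabulary,
                              random_gaussian_embeddings, train_word2vec)
from lexcnn.lexicon import Lexicon
from lexcnn.metrics import EvalReport, evaluate
from lexcnn.model import (AttentionCNNParams, backward_batch,
                          backward_batch_fasttext, forward_batch,
                          forward_batch_fasttext, init_params)
from lexcnn.preprocess import (CATEGORIES, PAD, RawPost, TokenizedPost,
                               assign_emoji_polarity, preprocess_corpus)
from lexcnn.weighting import (compute_class_frequencies, discriminability,
                              word_weights)

logger = logging.getLogger(__name__)

VARIANTS = ("liwc_cnn", "cnn_random", "cnn_word2vec", "fasttext_avg")


class TrainingError(ValueError):
    pass


@dataclass
class TrainConfig:
    """Hyperparameters; defaults follow the model family's reported setting."""

    d: int = 128                       # word-vector dimension
    learning_rate: float = 0.001
    windows: tuple[int, ...] = (2, 3, 5, 7)
    batch_size: int = 50
    dropout: float = 0.1
    kernels_per_window: int = 48
    l2_lambda: float = 0.1
    max_iterations: int = 600
    eval_every: int = 50
    k: int = 28                        # word classes kept by discriminability
    n: int = 100                       # padded sequence length
    seed: int = 0
    variant: str = "liwc_cnn"
    val_fraction: float = 0.1
    trainable_embeddings: bool = True
    w2v_epochs: int = 5
    w2v_window: int = 5

    def validate(self) -> None:
        if self.variant not in VARIANTS:
            raise TrainingError(f"variant {self.variant!r} not in {VARIANTS}")
        if not (0 <= self.dropout < 1):
            raise TrainingError("dropout must be in [0, 1)")
        if self.l2_lambda < 0:
            raise TrainingError("l2_lambda must be >= 0")
        positive = dict(d=self.d, learning_rate=self.learning_rate,
                        batch_size=self.batch_size, k=self.k, n=self.n,
                        max_iterations=self.max_iterations,
                        eval_every=self.eval_every,
                        kernels_per_window=self.kernels_per_window)
        for name, value in positive.items():
            if value <= 0:
                raise TrainingError(f"{name} must be positive, got {value}")


@dataclass
class TrainHistory:
    iterations: list[int] = field(default_factory=list)
    train_loss: list[float] = field(default_factory=list)
    train_acc: list[float] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)

    def record(self, iteration: int, train_loss: float, train_acc: float,
               val_acc: float) -> None:
        if self.iterations and iteration <= self.iterations[-1]:
            raise TrainingError("iteration indices must be strictly increasing")
        self.iterations.append(iteration)
        self.train_loss.append(train_loss)
        self.train_acc.append(train_acc)
        self.val_acc.append(val_acc)

    def write_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("iteration\ttrain_loss\ttrain_acc\tval_acc\n")
            for row in zip(self.iterations, self.train_loss,
                           self.train_acc, self.val_acc):
                fh.write("%d\t%.6g\t%.6g\t%.6g\n" % row)


@dataclass
class Checkpoint:
    """A trained model: parameters, embeddings, frozen weight table, config."""

    params: AttentionCNNParams
    emb: EmbeddingMatrix
    weight_table: dict[str, float] | None
    config: dict

    def save(self, path) -> None:
        model_mod.save_checkpoint(path, self.params, self.emb,
                                  self.weight_table, self.config)

    @classmethod
    def load(cls, path) -> "Checkpoint":
        params, emb, wt, config = model_mod.load_checkpoint(path)
        return cls(params, emb, wt, config)


def loss(probs: np.ndarray, labels_onehot: np.ndarray,
         params: AttentionCNNParams | None, l2_lambda: float) -> float:
    """Mean categorical cross-entropy plus (lambda/2)*||kernels, V||^2."""
    if probs.shape[0] == 0:
        raise TrainingError("loss of an empty batch is undefined")
    if l2_lambda < 0:
        raise TrainingError("l2_lambda must be >= 0")
    p_true = (probs * labels_onehot).sum(axis=1)
    if np.any(p_true <= 0):
        logger.warning("predicted probability 0 at the true class; clamping at 1e-12")
        p_true = np.clip(p_true, 1e-12, None)
    data = float(-np.log(p_true).mean())
    penalty = 0.0
    if params is not None and l2_lambda > 0:
        sq = float((params.V ** 2).sum())
        for h in params.windows:
            sq += float((params.kernels[h] ** 2).sum())
        penalty = 0.5 * l2_lambda * sq
    return data + penalty


def split_train_val(corpus: list, fraction: float, seed: int):
    """Label-stratified split into (train, validation); ``fraction`` is the
    training share.  Disjoint, union = input, reproducible by seed."""
    if not (0 < fraction < 1):
        raise TrainingError(f"fraction must be in (0, 1), got {fraction}")
    labels = [p.label for p in corpus]
    from collections import Counter
    for lab, cnt in Counter(labels).items():
        if cnt < 2:
            raise TrainingError(
                f"label {lab!r} has only {cnt} post(s); stratified split impossible")
    splitter = StratifiedShuffleSplit(n_splits=1, train_size=fraction,
                                      random_state=seed % (2 ** 31))
    train_idx, val_idx = next(splitter.split(np.zeros(len(corpus)), labels))
    train_idx, val_idx = sorted(train_idx), sorted(val_idx)
    return [corpus[i] for i in train_idx], [corpus[i] for i in val_idx]


def select_best_iteration(history: TrainHistory) -> int:
    """Recorded iteration with maximal validation accuracy; earliest on ties."""
    if not history.iterations:
        raise TrainingError("empty training history")
    best = int(np.argmax(history.val_acc))  # argmax returns the first maximum
    return history.iterations[best]


class _Adam:
    def __init__(self, lr: float):
        self.lr = lr
        self.t = 0
        self.state: dict[str, tuple[np.ndarray, np.ndarray]] = {}

    def step(self, updates: dict[str, tuple[np.ndarray, np.ndarray]],
             b1: float = 0.9, b2: float = 0.999, eps: float = 1e-8) -> None:
        self.t += 1
        for key, (param, grad) in updates.items():
            if key not in self.state:
                self.state[key] = (np.zeros_like(param), np.zeros_like(param))
            m, v = self.state[key]
            m[...] = b1 * m + (1 - b1) * grad
            v[...] = b2 * v + (1 - b2) * grad * grad
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            param -= self.lr * mhat / (np.sqrt(vhat) + eps)


class DictWeightTable:
    """Frozen token -> weight mapping (from a checkpoint); default weight 1."""

    def __init__(self, table: dict[str, float]):
        self._table = table

    def weight(self, token: str) -> float:
        return self._table.get(token, 1.0)

    __getitem__ = weight

    def weights_for(self, post: TokenizedPost) -> np.ndarray:
        return np.array([self.weight(t) for t in post.tokens])


def train(corpus: list[RawPost], lexicon: Lexicon | None,
          config: TrainConfig) -> tuple[Checkpoint, TrainHistory]:
    """Full training run on a labeled raw corpus; deterministic given seed.

    Runs preprocessing and (for the attention variant) the weighting pipeline
    once, builds the embeddings the variant prescribes, then iterates
    mini-batch Adam on the regularized cross-entropy.  Returns the checkpoint
    of the best-validation iteration plus the full history.
    """
    config.validate()
    if config.variant == "liwc_cnn" and lexicon is None:
        raise TrainingError("the attention variant requires a lexicon")
    rng = np.random.default_rng(config.seed)

    polarity_map = assign_emoji_polarity(corpus)
    tokenized, _ = preprocess_corpus(corpus, config.n, polarity_map)

    # Attention weights: computed once, before any gradient step.
    weights = None
    weight_dict = None
    if config.variant == "liwc_cnn":
        freq = compute_class_frequencies(tokenized, lexicon)
        disc = discriminability(freq, config.k)
        weights = word_weights(lexicon, disc)

    if config.variant == "cnn_random":
        vocab = build_vocabulary(tokenized)
        emb = random_gaussian_embeddings(vocab, config.d, config.seed)
    else:
        emb = train_word2vec(tokenized, config.d, config.seed,
                             window=config.w2v_window, epochs=config.w2v_epochs)
    if weights is not None:
        weight_dict = weights.for_vocabulary(emb.vocabulary)

    train_posts, val_posts = split_train_val(tokenized, 1 - config.val_fraction,
                                             config.seed)

    cat_index = {c: i for i, c in enumerate(CATEGORIES)}
    fasttext = config.variant == "fasttext_avg"
    params = init_params(config.d, config.windows, config.kernels_per_window,
                         config.seed, config.dropout, fasttext=fasttext)

    def pack(posts):
        idx = np.stack([emb.indices(p) for p in posts])
        y = np.zeros((len(posts), model_mod.N_CLASSES))
        y[np.arange(len(posts)), [cat_index[p.label] for p in posts]] = 1.0
        if weights is not None:
            a = np.stack([weights.weights_for(p) for p in posts])
        else:
            a = np.ones(idx.shape)
        mask = (idx != emb.index[PAD]).astype(float)
        return idx, a, y, mask

    tr_idx, tr_a, tr_y, tr_mask = pack(train_posts)
    va_idx, va_a, va_y, va_mask = pack(val_posts)
    pad_row = emb.index[PAD]

    def eval_forward(idx, a, mask):
        X = emb.vectors[idx]
        if fasttext:
            probs, _ = forward_batch_fasttext(X, mask, params)
        else:
            probs, _ = forward_batch(X, a, params)
        return probs

    opt = _Adam(config.learning_rate)
    history = TrainHistory()
    snapshots: dict[int, tuple[AttentionCNNParams, np.ndarray]] = {}
    N = len(train_posts)
    order = rng.permutation(N)
    cursor = 0

    def record(iteration):
        tr_probs = eval_forward(tr_idx, tr_a, tr_mask)
        va_probs = eval_forward(va_idx, va_a, va_mask)
        tl = loss(tr_probs, tr_y, None if fasttext else params, config.l2_lambda)
        ta = float((tr_probs.argmax(1) == tr_y.argmax(1)).mean())
        va = float((va_probs.argmax(1) == va_y.argmax(1)).mean())
        history.record(iteration, tl, ta, va)
        snapshots[iteration] = (copy.deepcopy(params), emb.vectors.copy())
        logger.info("iter %d: train loss %.4f acc %.3f | val acc %.3f",
                    iteration, tl, ta, va)

    for iteration in range(1, config.max_iterations + 1):
        if cursor + config.batch_size > N:
            order = rng.permutation(N)
            cursor = 0
        batch = order[cursor:cursor + config.batch_size]
        cursor += config.batch_size

        X = emb.vectors[tr_idx[batch]]
        y = tr_y[batch]
        if fasttext:
            probs, cache = forward_batch_fasttext(X, tr_mask[batch], params)
            grads = backward_batch_fasttext(cache, y, params, config.l2_lambda,
                                            config.trainable_embeddings)
        else:
            dmask = None
            if config.dropout > 0:
                feat = params.V.shape[1]
                dmask = (rng.random((len(batch), feat)) >= config.dropout) \
                    / (1 - config.dropout)
            probs, cache = forward_batch(X, tr_a[batch], params, dmask)
            grads = backward_batch(cache, y, params, config.l2_lambda,
                                   config.trainable_embeddings)
        if not np.isfinite(probs).all():
            raise TrainingError(
                "non-finite loss/probabilities at iteration %d; "
                "consider lowering the learning rate" % iteration)

        updates = {"V": (params.V, grads["V"]),
                   "b_out": (params.b_out, grads["b_out"])}
        for h in params.windows:
            updates[f"kernel_{h}"] = (params.kernels[h], grads["kernels"][h])
            updates[f"bias_{h}"] = (params.biases[h], grads["biases"][h])
        if config.trainable_embeddings and "dX" in grads:
            dE = np.zeros_like(emb.vectors)
            np.add.at(dE, tr_idx[batch].reshape(-1),
                      grads["dX"].reshape(-1, emb.d))
            dE[pad_row] = 0.0  # padding stays the zero vector
            updates["emb"] = (emb.vectors, dE)
        opt.step(updates)

        if iteration % config.eval_every == 0 or iteration == config.max_iterations:
            record(iteration)

    best_iter = select_best_iteration(history)
    best_params, best_emb_vectors = snapshots[best_iter]
    best_emb = EmbeddingMatrix(emb.vocabulary, best_emb_vectors)
    cfg = asdict(config)
    cfg["windows"] = list(config.windows)
    cfg["polarity_map"] = polarity_map
    cfg["best_iteration"] = best_iter
    checkpoint = Checkpoint(best_params, best_emb, weight_dict, cfg)
    return checkpoint, history


def predict(checkpoint: Checkpoint, corpus: list[RawPost]) -> list[str]:
    """Predicted triage labels for raw posts, using the checkpoint's own
    preprocessing configuration (sequence length and emoji polarity map)."""
    cfg = checkpoint.config
    tokenized, _ = preprocess_corpus(corpus, cfg["n"],
                                     cfg.get("polarity_map") or {})
    fasttext = cfg.get("variant") == "fasttext_avg"
    idx = np.stack([checkpoint.emb.indices(p) for p in tokenized])
    X = checkpoint.emb.vectors[idx]
    if fasttext:
        mask = (idx != checkpoint.emb.index[PAD]).astype(float)
        probs, _ = forward_batch_fasttext(X, mask, checkpoint.params)
    else:
        if checkpoint.weight_table is not None:
            wt = DictWeightTable(checkpoint.weight_table)
            a = np.stack([wt.weights_for(p) for p in tokenized])
        else:
            a = np.ones(idx.shape)
        probs, _ = forward_batch(X, a, checkpoint.params)
    return [CATEGORIES[i] for i in probs.argmax(axis=1)]


def evaluate_checkpoint(checkpoint: Checkpoint,
                        corpus: list[RawPost]) -> EvalReport:
    if any(p.label is None for p in corpus):
        raise TrainingError("evaluation requires labels on every post")
    pred = predict(checkpoint, corpus)
    return evaluate([p.label for p in corpus], pred)
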