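"""Input word vectors: corpus-trained skip-gram vectors or Gaussian init.

`train_word2vec` is a NumPy implementation of skip-gram with negative
sampling: dynamic context windows, a unigram^(3/4) negative-sampling table,
and linearly decaying learning rate, trained single-threaded so a fixed seed
reproduces the matrix bit for bit.  Updates are batched per sentence (all
centre/context pairs of one sentence share a parameter snapshot), which is
the usual mini-batch relaxation of the classic per-pair update.

The PAD marker's vector is fixed to zero after initialization (and kept
frozen during classifier training) so padding positions cannot inject signal.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from lexcnn.preprocess import PAD, RESERVED_TOKENS, UNK, TokenizedPost


class EmbeddingError(ValueError):
    pass


@dataclass
class EmbeddingMatrix:
    vocabulary: list[str]
    vectors: np.ndarray  # (|V|, d)

    def __post_init__(self) -> None:
        if self.vectors.ndim != 2 or self.vectors.shape[0] != len(self.vocabulary):
            raise EmbeddingError("vectors must be |V| x d")
        if not np.isfinite(self.vectors).all():
            raise EmbeddingError("non-finite embedding values")
        self.index = {tok: i for i, tok in enumerate(self.vocabulary)}
        if len(self.index) != len(self.vocabulary):
            raise EmbeddingError("duplicate vocabulary tokens")

    @property
    def d(self) -> int:
        return self.vectors.shape[1]

    def row(self, token: str) -> np.ndarray:
        """Vector of a token; unknown tokens map to the UNK row."""
        return self.vectors[self.index.get(token, self.index[UNK])]

    def lookup(self, post: TokenizedPost) -> np.ndarray:
        """n x d matrix whose row j is the vector of token j."""
        idx = [self.index.get(t, self.index[UNK]) for t in post.tokens]
        return self.vectors[idx]

    def indices(self, post: TokenizedPost) -> np.ndarray:
        return np.array([self.index.get(t, self.index[UNK]) for t in post.tokens])


def build_vocabulary(corpus: Iterable[TokenizedPost]) -> list[str]:
    """Reserved markers first, then corpus tokens by descending frequency."""
    counts: Counter[str] = Counter()
    for post in corpus:
        counts.update(t for t in post.tokens[:post.true_length] if t != PAD)
    ordered = sorted(counts, key=lambda t: (-counts[t], t))
    return list(RESERVED_TOKENS) + [t for t in ordered if t not in RESERVED_TOKENS]


def random_gaussian_embeddings(vocabulary: list[str], d: int,
                               seed: int) -> EmbeddingMatrix:
    """i.i.d. Normal(0, 1) vectors (the traditional-CNN initializer).

    The PAD row is zeroed after sampling per the padding contract.
    """
    if d < 1:
        raise EmbeddingError(f"embedding dimension must be >= 1, got {d}")
    rng = np.random.default_rng(seed)
    vectors = rng.standard_normal((len(vocabulary), d))
    emb = EmbeddingMatrix(list(vocabulary), vectors)
    emb.vectors[emb.index[PAD]] = 0.0
    return emb


def train_word2vec(corpus: Iterable[TokenizedPost], d: int, seed: int,
                   window: int = 5, epochs: int = 5, negatives: int = 5,
                   min_count: int = 1, lr: float = 0.025) -> EmbeddingMatrix:
    """Skip-gram negative-sampling vectors trained on the tokenized corpus.

    Tokens below ``min_count`` keep their Gaussian-initialized fallback
    vector (scaled to the word2vec init range).  Deterministic given seed.
    """
    posts = list(corpus)
    if not posts:
        raise EmbeddingError("cannot train word vectors on an empty corpus")
    if d < 2:
        raise EmbeddingError(f"embedding dimension must be >= 2, got {d}")

    vocabulary = build_vocabulary(posts)
    index = {tok: i for i, tok in enumerate(vocabulary)}
    counts = np.zeros(len(vocabulary))
    sentences: list[np.ndarray] = []
    for post in posts:
        toks = [t for t in post.tokens[:post.true_length] if t != PAD]
        if toks:
            ids = np.array([index[t] for t in toks])
            sentences.append(ids)
            np.add.at(counts, ids, 1)

    rng = np.random.default_rng(seed)
    W_in = (rng.random((len(vocabulary), d)) - 0.5) / d
    W_out = np.zeros((len(vocabulary), d))

    trained = counts >= min_count
    # Negative-sampling distribution over trained tokens: unigram^0.75.
    p_neg = np.where(trained, counts, 0.0) ** 0.75
    if p_neg.sum() == 0:
        raise EmbeddingError("no token reaches min_count")
    p_neg /= p_neg.sum()
    neg_ids = np.flatnonzero(p_neg)
    neg_p = p_neg[neg_ids]

    total_steps = max(1, epochs * len(sentences))
    step = 0
    for _ in range(epochs):
        for ids in sentences:
            step += 1
            alpha = lr * max(1e-4, 1.0 - step / total_steps)
            L = len(ids)
            if L < 2:
                continue
            # Dynamic windows: pair (centre, context) lists for the sentence.
            b = rng.integers(1, window + 1, size=L)
            centers, contexts = [], []
            for i in range(L):
                lo, hi = max(0, i - b[i]), min(L, i + b[i] + 1)
                for j in range(lo, hi):
                    if j != i:
                        centers.append(ids[i])
                        contexts.append(ids[j])
            c = np.array(centers)
            o = np.array(contexts)
            keep = trained[c] & trained[o]
            c, o = c[keep], o[keep]
            if len(c) == 0:
                continue
            negs = neg_ids[rng.choice(len(neg_ids), size=(len(c), negatives), p=neg_p)]

            v_c = W_in[c]                                  # (P, d)
            u_o = W_out[o]                                 # (P, d)
            u_n = W_out[negs]                              # (P, K, d)
            g_pos = _sigmoid((v_c * u_o).sum(1)) - 1.0     # (P,)
            g_neg = _sigmoid(np.einsum("pd,pkd->pk", v_c, u_n))  # (P, K)

            grad_c = g_pos[:, None] * u_o + np.einsum("pk,pkd->pd", g_neg, u_n)
            np.add.at(W_in, c, -alpha * grad_c)
            np.add.at(W_out, o, -alpha * g_pos[:, None] * v_c)
            flat_negs = negs.reshape(-1)
            flat_grad = (g_neg[:, :, None] * v_c[:, None, :]).reshape(-1, d)
            np.add.at(W_out, flat_negs, -alpha * flat_grad)

    emb = EmbeddingMatrix(vocabulary, W_in)
    emb.vectors[emb.index[PAD]] = 0.0
    return emb


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


# --------------------------------------------------------- word2vec text I/O

def write_word2vec_text(emb: EmbeddingMatrix, path) -> None:
    """word2vec text format: header "count dim", then "token v1 ... vd"."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{len(emb.vocabulary)} {emb.d}\n")
        for tok, vec in zip(emb.vocabulary, emb.vectors):
            vals = " ".join(f"{v:.8g}" for v in vec)
            fh.write(f"{tok} {vals}\n")


def read_word2vec_text(path) -> EmbeddingMatrix:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise EmbeddingError(f"{path}: malformed word2vec header")
        count, d = int(header[0]), int(header[1])
        vocabulary, rows = [], []
        for line in fh:
            parts = line.rstrip("\n").split(" ")
            if len(parts) != d + 1:
                raise EmbeddingError(f"{path}: bad vector line for {parts[0]!r}")
            vocabulary.append(parts[0])
            rows.append([float(v) for v in parts[1:]])
    if len(vocabulary) != count:
        raise EmbeddingError(f"{path}: header count {count} != {len(vocabulary)} rows")
    return EmbeddingMatrix(vocabulary, np.array(rows))
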