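"""Forward computation of the attention-weighted text CNN and its baselines.

Architecture (Kim-style, one convolution block per window size h):

    lookup -> attention scaling M = diag(a) X -> for each h: sigmoid
    convolution over all length-h windows -> max-over-time pooling ->
    concatenate -> dense + softmax over the 4 triage categories.

The logistic sigmoid is used as the convolution activation (an unusual but
deliberate fidelity choice of this model family).  The attention layer is the
single difference from the traditional-CNN baseline: forcing every a_i to 1
reproduces the baseline bit for bit, which is the ablation contract tests
rely on.

Baselines:
  * ``cnn_random`` / ``cnn_word2vec`` — the same network with unit weights
    and Gaussian / skip-gram initial embeddings respectively;
  * ``fasttext_avg`` — mean of the non-pad token vectors fed straight into
    the dense softmax layer (a bag-of-embeddings linear classifier).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from lexcnn.embedding import EmbeddingMatrix
from lexcnn.preprocess import CATEGORIES, TokenizedPost
from lexcnn.weighting import WordWeightTable

N_CLASSES = 4

CHECKPOINT_VERSION = 1

BASELINE_VARIANTS = ("fasttext_avg", "cnn_random", "cnn_word2vec")


class ModelError(ValueError):
    pass


@dataclass
class AttentionCNNParams:
    """Trainable parameters: per-window kernels/biases plus the dense layer.

    For the ``fasttext_avg`` variant ``windows`` is empty and V acts on the
    averaged embedding directly (shape 4 x d).
    """

    windows: tuple[int, ...]
    kernels: dict[int, np.ndarray] = field(default_factory=dict)  # h -> (m, h, d)
    biases: dict[int, np.ndarray] = field(default_factory=dict)   # h -> (m,)
    V: np.ndarray = None
    b_out: np.ndarray = None
    dropout: float = 0.1

    def validate(self) -> None:
        if self.V.shape[0] != N_CLASSES or self.b_out.shape != (N_CLASSES,):
            raise ModelError("output layer must have exactly 4 units")
        for h in self.windows:
            if h not in self.kernels or self.kernels[h].shape[0] < 1:
                raise ModelError(f"window {h} has no kernels")
        arrays = [self.V, self.b_out, *self.kernels.values(), *self.biases.values()]
        if not all(np.isfinite(a).all() for a in arrays):
            raise ModelError("non-finite parameter values")

    def n_filters(self) -> int:
        return sum(self.kernels[h].shape[0] for h in self.windows)


def init_params(d: int, windows: tuple[int, ...], m: int, seed: int,
                dropout: float = 0.1, fasttext: bool = False) -> AttentionCNNParams:
    """Small-random (Glorot-scaled) initialization of all trainable weights."""
    rng = np.random.default_rng(seed)
    if fasttext:
        V = rng.normal(0, np.sqrt(2.0 / (d + N_CLASSES)), (N_CLASSES, d))
        return AttentionCNNParams(windows=(), V=V,
                                  b_out=np.zeros(N_CLASSES), dropout=0.0)
    kernels, biases = {}, {}
    for h in windows:
        scale = np.sqrt(2.0 / (h * d + 1))
        kernels[h] = rng.normal(0, scale, (m, h, d))
        biases[h] = np.zeros(m)
    feat = len(windows) * m
    V = rng.normal(0, np.sqrt(2.0 / (feat + N_CLASSES)), (N_CLASSES, feat))
    return AttentionCNNParams(tuple(windows), kernels, biases, V,
                              np.zeros(N_CLASSES), dropout)


def attention_weight(X: np.ndarray, a: np.ndarray) -> np.ndarray:
    """Row-wise scaling M[i] = a[i] * X[i]."""
    a = np.asarray(a, dtype=float)
    if a.shape[0] != X.shape[0]:
        raise ModelError(
            f"weight vector length {a.shape[0]} != sequence length {X.shape[0]}")
    return a[:, None] * X


def conv_features(M: np.ndarray, kernel: np.ndarray, bias: np.ndarray) -> np.ndarray:
    """Sigmoid convolution feature maps, shape (n - h + 1, m).

    Position j of filter f is sigmoid(<kernel[f], M[j:j+h]> + bias[f]) where
    <.,.> is the Frobenius inner product over the h x d window.
    """
    m, h, d = kernel.shape
    n = M.shape[0]
    if n < h:
        raise ModelError(f"sequence length {n} shorter than kernel window {h}")
    win = np.lib.stride_tricks.sliding_window_view(M, (h, d)).reshape(n - h + 1, h * d)
    pre = win @ kernel.reshape(m, h * d).T + bias
    return _sigmoid(pre)


def max_pool(feature_maps: list[np.ndarray]) -> np.ndarray:
    """Max over positions per filter, concatenated in fixed (window, filter) order."""
    if not feature_maps:
        raise ModelError("no feature maps to pool (post shorter than every window)")
    pooled = []
    for fm in feature_maps:
        if fm.shape[0] == 0:
            raise ModelError("empty feature map")
        pooled.append(fm.max(axis=0))
    return np.concatenate(pooled)


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def forward(post: TokenizedPost, emb: EmbeddingMatrix,
            weights: WordWeightTable | None,
            params: AttentionCNNParams) -> np.ndarray:
    """Class probability 4-vector for one post (dropout disabled).

    ``weights=None`` means unit attention (the traditional-CNN path).
    Unknown tokens use the UNK embedding row.  Windows longer than the
    sequence are skipped; if every window is skipped a ModelError is raised.
    """
    params.validate()
    X = emb.lookup(post)
    a = weights.weights_for(post) if weights is not None else np.ones(len(post.tokens))
    M = attention_weight(X, a)
    maps = []
    for h in params.windows:
        if M.shape[0] < h:
            import logging
            logging.getLogger(__name__).warning(
                "post %r shorter than window %d; window skipped", post.post_id, h)
            continue
        maps.append(conv_features(M, params.kernels[h], params.biases[h]))
    pooled = max_pool(maps)
    return softmax(params.V @ pooled + params.b_out)


def baseline_forward(post: TokenizedPost, emb: EmbeddingMatrix,
                     params: AttentionCNNParams, variant: str) -> np.ndarray:
    """Comparison systems: averaged-embedding softmax or unit-weight CNN."""
    if variant == "fasttext_avg":
        params.validate()
        X = emb.lookup(post)
        if post.true_length > 0:
            avg = X[:post.true_length].mean(axis=0)
        else:
            avg = np.zeros(emb.d)
        return softmax(params.V @ avg + params.b_out)
    if variant in ("cnn_random", "cnn_word2vec"):
        return forward(post, emb, None, params)
    raise ModelError(f"unknown baseline variant {variant!r}; "
                     f"expected one of {BASELINE_VARIANTS}")


# ------------------------------------------------------- batched internals

def forward_batch(X: np.ndarray, a: np.ndarray, params: AttentionCNNParams,
                  dropout_mask: np.ndarray | None = None) -> tuple[np.ndarray, dict]:
    """Batched forward pass with cache for backprop.

    X: (B, n, d); a: (B, n).  Returns (probs (B, 4), cache).
    ``dropout_mask`` is an inverted-dropout mask over the pooled vector
    (training only; None at inference).
    """
    B, n, d = X.shape
    M = a[:, :, None] * X
    cache: dict = {"X": X, "a": a, "maps": {}, "wins": {}, "argmax": {}}
    pooled_parts = []
    for h in params.windows:
        m = params.kernels[h].shape[0]
        L = n - h + 1
        if L < 1:
            raise ModelError(f"sequence length {n} shorter than window {h}")
        win = np.lib.stride_tricks.sliding_window_view(
            M, (h, d), axis=(1, 2)).reshape(B, L, h * d)
        pre = win @ params.kernels[h].reshape(m, h * d).T + params.biases[h]
        act = _sigmoid(pre)
        amax = act.argmax(axis=1)                     # (B, m)
        cache["wins"][h] = win
        cache["maps"][h] = act
        cache["argmax"][h] = amax
        pooled_parts.append(np.take_along_axis(act, amax[:, None, :], axis=1)[:, 0, :])
    pooled = np.concatenate(pooled_parts, axis=1)
    cache["pooled"] = pooled
    if dropout_mask is not None:
        pooled = pooled * dropout_mask
    cache["dropout_mask"] = dropout_mask
    cache["pooled_dropped"] = pooled
    logits = pooled @ params.V.T + params.b_out
    probs = softmax(logits)
    cache["probs"] = probs
    return probs, cache


def backward_batch(cache: dict, labels_onehot: np.ndarray,
                   params: AttentionCNNParams, l2: float,
                   train_embeddings: bool = False) -> dict:
    """Gradients of (mean cross-entropy + (l2/2)*||kernels, V||^2).

    Returns a dict with 'V', 'b_out', per-window 'kernels'/'biases', and —
    when ``train_embeddings`` — 'dX' (B, n, d), the gradient w.r.t. the
    looked-up (unweighted) embedding rows.
    """
    X, a = cache["X"], cache["a"]
    B, n, d = X.shape
    dlogits = (cache["probs"] - labels_onehot) / B          # (B, 4)
    grads: dict = {
        "V": dlogits.T @ cache["pooled_dropped"] + l2 * params.V,
        "b_out": dlogits.sum(axis=0),
        "kernels": {}, "biases": {},
    }
    dpooled = dlogits @ params.V                             # (B, feat)
    if cache["dropout_mask"] is not None:
        dpooled = dpooled * cache["dropout_mask"]
    dM = np.zeros_like(X) if train_embeddings else None
    offset = 0
    for h in params.windows:
        m = params.kernels[h].shape[0]
        act = cache["maps"][h]                               # (B, L, m)
        L = act.shape[1]
        dp = dpooled[:, offset:offset + m]                   # (B, m)
        offset += m
        dact = np.zeros_like(act)
        np.put_along_axis(dact, cache["argmax"][h][:, None, :], dp[:, None, :], axis=1)
        dpre = dact * act * (1.0 - act)                      # (B, L, m)
        win = cache["wins"][h]                               # (B, L, h*d)
        dW = np.einsum("blm,blk->mk", dpre, win).reshape(m, h, d)
        grads["kernels"][h] = dW + l2 * params.kernels[h]
        grads["biases"][h] = dpre.sum(axis=(0, 1))
        if train_embeddings:
            dwin = (dpre @ params.kernels[h].reshape(m, h * d)).reshape(B, L, h, d)
            for j in range(h):
                dM[:, j:j + L, :] += dwin[:, :, j, :]
    if train_embeddings:
        grads["dX"] = a[:, :, None] * dM
    return grads


def forward_batch_fasttext(X: np.ndarray, mask: np.ndarray,
                           params: AttentionCNNParams) -> tuple[np.ndarray, dict]:
    """Averaged-embedding softmax, batched.  mask: (B, n) 1 for non-pad."""
    counts = np.maximum(mask.sum(axis=1, keepdims=True), 1.0)
    avg = (X * mask[:, :, None]).sum(axis=1) / counts        # (B, d)
    probs = softmax(avg @ params.V.T + params.b_out)
    return probs, {"X": X, "mask": mask, "avg": avg, "counts": counts, "probs": probs}


def backward_batch_fasttext(cache: dict, labels_onehot: np.ndarray,
                            params: AttentionCNNParams, l2: float,
                            train_embeddings: bool = False) -> dict:
    B = cache["X"].shape[0]
    dlogits = (cache["probs"] - labels_onehot) / B
    grads = {"V": dlogits.T @ cache["avg"] + l2 * params.V,
             "b_out": dlogits.sum(axis=0), "kernels": {}, "biases": {}}
    if train_embeddings:
        davg = dlogits @ params.V                            # (B, d)
        grads["dX"] = (davg[:, None, :] / cache["counts"][:, :, None]) \
            * cache["mask"][:, :, None]
    return grads


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


# ------------------------------------------------------------- checkpointing

def save_checkpoint(path, params: AttentionCNNParams, emb: EmbeddingMatrix,
                    weight_table: dict[str, float] | None, config: dict) -> None:
    """Single self-describing .npz archive with a version field."""
    arrays: dict[str, np.ndarray] = {
        "V": params.V, "b_out": params.b_out, "emb": emb.vectors,
    }
    for h in params.windows:
        arrays[f"kernel_{h}"] = params.kernels[h]
        arrays[f"bias_{h}"] = params.biases[h]
    meta = {
        "version": CHECKPOINT_VERSION,
        "windows": list(params.windows),
        "dropout": params.dropout,
        "vocabulary": emb.vocabulary,
        "weight_table": weight_table,
        "config": config,
        "categories": list(CATEGORIES),
    }
    arrays["meta"] = np.array(json.dumps(meta))
    np.savez(path, **arrays)


def load_checkpoint(path) -> tuple[AttentionCNNParams, EmbeddingMatrix,
                                   dict[str, float] | None, dict]:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        if meta.get("version") != CHECKPOINT_VERSION:
            raise ModelError(f"unsupported checkpoint version {meta.get('version')}")
        windows = tuple(meta["windows"])
        params = AttentionCNNParams(
            windows=windows,
            kernels={h: data[f"kernel_{h}"] for h in windows},
            biases={h: data[f"bias_{h}"] for h in windows},
            V=data["V"], b_out=data["b_out"], dropout=meta["dropout"],
        )
        emb = EmbeddingMatrix(meta["vocabulary"], data["emb"])
    return params, emb, meta["weight_table"], meta["config"]
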