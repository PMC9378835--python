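"""Word-class discriminability weighting: the core of the method.

For a labeled corpus and an LIWC-style lexicon, each semantic word class l
gets a usage frequency per triage category c:

    TF(l, c) = (# non-pad tokens in category-c posts matching l)
               / (total non-pad tokens in category-c posts)

Rows are max-normalized, TF'(l, c) = TF(l, c) / max_c TF(l, c), and the
spread of the normalized row across the four categories,

    delta_l = sqrt( sum_c (TF'(l, c) - mu_l)^2 ),   mu_l = mean_c TF'(l, c),

ranks the classes: a class used very unevenly across categories separates
them well.  The top-k classes by delta become linguistic features, and every
token i is assigned an attention weight

    a_i = exp(delta_best) / sum_{l in selected} exp(delta_l) + 1

where delta_best is the largest delta among the selected classes the token
belongs to; tokens matching no selected class (including out-of-lexicon
tokens and reserved markers) get a_i = 1.  The sum of squared deviations is
deliberately not divided by the category count: dividing would rescale every
delta by the same factor — leaving the ranking intact — but it would change
the softmax shares and hence the weights, so the convention is load-bearing
and fixed here.

Per-post linguistic feature vectors LGF(l, p) — the fraction of the post's
tokens belonging to class l, over the selected classes — are exported for
external use; the classifier itself consumes only the attention weights.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from lexcnn.lexicon import Lexicon
from lexcnn.preprocess import CATEGORIES, PAD, TokenizedPost

logger = logging.getLogger(__name__)


class WeightingError(ValueError):
    pass


@dataclass
class ClassFrequencyTable:
    categories: tuple[str, ...]
    class_ids: list[int]              # semantic classes, ascending id
    tf: np.ndarray                    # (n_classes, n_categories), values in [0, 1]
    token_totals: np.ndarray          # per-category non-pad token counts

    def row(self, class_id: int) -> np.ndarray:
        return self.tf[self.class_ids.index(class_id)]


@dataclass
class ClassDiscriminability:
    class_ids: list[int]
    tf_norm: np.ndarray               # TF'(l, c)
    mu: np.ndarray                    # per-class mean of TF'
    sd: np.ndarray                    # per-class delta_l >= 0
    selected: list[int]               # top-k class ids, descending delta
    k: int

    def sd_of(self, class_id: int) -> float:
        return float(self.sd[self.class_ids.index(class_id)])


def compute_class_frequencies(corpus: Iterable[TokenizedPost],
                              lexicon: Lexicon,
                              categories: tuple[str, ...] = CATEGORIES,
                              ) -> ClassFrequencyTable:
    """Per-class, per-category token usage frequencies TF(l, c).

    Pad tokens are excluded from both numerator and denominator.  A category
    with zero tokens yields a zero column (with a warning).
    """
    posts = list(corpus)
    if not posts or any(p.label is None for p in posts):
        raise WeightingError("class frequencies require a non-empty, fully labeled corpus")
    class_ids = lexicon.semantic_class_ids()
    if not class_ids:
        raise WeightingError("lexicon has no semantic classes")
    row_of = {cid: i for i, cid in enumerate(class_ids)}
    cat_of = {c: j for j, c in enumerate(categories)}

    counts = np.zeros((len(class_ids), len(categories)))
    totals = np.zeros(len(categories))
    for post in posts:
        j = cat_of[post.label]
        for tok in post.tokens[:post.true_length]:
            if tok == PAD:
                continue
            totals[j] += 1
            for cid in lexicon.match(tok):
                if cid in row_of:
                    counts[row_of[cid], j] += 1

    tf = np.zeros_like(counts)
    nonzero = totals > 0
    tf[:, nonzero] = counts[:, nonzero] / totals[nonzero]
    for j, cat in enumerate(categories):
        if not nonzero[j]:
            logger.warning("category %r has zero tokens; its TF column is 0", cat)
    return ClassFrequencyTable(tuple(categories), class_ids, tf, totals)


def discriminability(freq: ClassFrequencyTable, k: int) -> ClassDiscriminability:
    """Max-normalize TF rows and rank classes by the spread delta_l; select top-k.

    Zero rows stay zero and get delta = 0.  Ties in the top-k cut are broken
    by ascending class id, for determinism.
    """
    if k < 1:
        raise WeightingError(f"k must be >= 1, got {k}")
    row_max = freq.tf.max(axis=1)
    tf_norm = np.zeros_like(freq.tf)
    nz = row_max > 0
    tf_norm[nz] = freq.tf[nz] / row_max[nz, None]
    mu = tf_norm.mean(axis=1)
    sd = np.sqrt(((tf_norm - mu[:, None]) ** 2).sum(axis=1))

    k_eff = min(k, len(freq.class_ids))
    if k_eff < k:
        logger.warning("k=%d exceeds the %d semantic classes; selecting all",
                       k, len(freq.class_ids))
    # Descending delta, ties by ascending class id.
    order = sorted(range(len(freq.class_ids)),
                   key=lambda i: (-sd[i], freq.class_ids[i]))
    selected = [freq.class_ids[i] for i in order[:k_eff]]
    return ClassDiscriminability(freq.class_ids, tf_norm, mu, sd, selected, k)


class WordWeightTable:
    """Token -> attention weight a_i, derived from a lexicon and a selection.

    Deterministic given (lexicon, discriminability); weights are computed on
    demand and memoized, so any vocabulary can be scored.
    """

    def __init__(self, lexicon: Lexicon, disc: ClassDiscriminability):
        if not disc.selected:
            raise WeightingError("word weights require a non-empty selected class set")
        self._lexicon = lexicon
        self._sd = {cid: disc.sd_of(cid) for cid in disc.selected}
        self._denom = float(np.sum(np.exp(list(self._sd.values()))))
        self._cache: dict[str, float] = {}

    def weight(self, token: str) -> float:
        w = self._cache.get(token)
        if w is None:
            matched = self._lexicon.match(token) & self._sd.keys()
            if matched:
                best = max(self._sd[cid] for cid in matched)
                w = float(np.exp(best) / self._denom + 1.0)
            else:
                w = 1.0
            self._cache[token] = w
        return w

    __getitem__ = weight

    def for_vocabulary(self, vocabulary: Iterable[str]) -> dict[str, float]:
        return {tok: self.weight(tok) for tok in vocabulary}

    def weights_for(self, post: TokenizedPost) -> np.ndarray:
        return np.array([self.weight(t) for t in post.tokens])


def word_weights(lexicon: Lexicon, disc: ClassDiscriminability) -> WordWeightTable:
    """Attention weight table; 1 for tokens outside every selected class."""
    return WordWeightTable(lexicon, disc)


def lgf_features(post: TokenizedPost, lexicon: Lexicon,
                 disc: ClassDiscriminability) -> np.ndarray:
    """Per-post fraction of tokens in each selected class (selection order).

    A post with no real tokens yields the all-zero vector (with a warning).
    """
    vec = np.zeros(len(disc.selected))
    if post.true_length == 0:
        logger.warning("post %r has no tokens; LGF vector is all-zero", post.post_id)
        return vec
    pos = {cid: i for i, cid in enumerate(disc.selected)}
    for tok in post.tokens[:post.true_length]:
        if tok == PAD:
            continue
        for cid in lexicon.match(tok):
            if cid in pos:
                vec[pos[cid]] += 1
    return vec / post.true_length


def export_discriminability_tsv(freq: ClassFrequencyTable,
                                disc: ClassDiscriminability,
                                lexicon: Lexicon, path) -> None:
    """Ranked class table: name, per-category TF, delta, selected flag."""
    order = sorted(range(len(disc.class_ids)),
                   key=lambda i: (-disc.sd[i], disc.class_ids[i]))
    sel = set(disc.selected)
    with open(path, "w", encoding="utf-8") as fh:
        cats = "\t".join(f"tf_{c}" for c in freq.categories)
        fh.write(f"class_id\tclass_name\t{cats}\tdelta\tselected\n")
        for i in order:
            cid = disc.class_ids[i]
            tfs = "\t".join(f"{v:.6g}" for v in freq.tf[i])
            fh.write(f"{cid}\t{lexicon.classes[cid].name}\t{tfs}\t"
                     f"{disc.sd[i]:.6g}\t{int(cid in sel)}\n")


def export_lgf_csv(posts: Iterable[TokenizedPost], lexicon: Lexicon,
                   disc: ClassDiscriminability, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        names = ",".join(f"lgf_{cid}" for cid in disc.selected)
        fh.write(f"post_id,label,{names}\n")
        for post in posts:
            vec = lgf_features(post, lexicon, disc)
            vals = ",".join(f"{v:.6g}" for v in vec)
            fh.write(f"{post.post_id},{post.label or ''},{vals}\n")
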