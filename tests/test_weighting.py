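"""Class frequencies, discriminability ranking, attention weights, LGF."""

import math

import numpy as np
import pytest

from conftest import make_post
from lexcnn.lexicon import Lexicon, WordClass
from lexcnn.preprocess import CATEGORIES
from lexcnn.weighting import (ClassFrequencyTable, WeightingError,
                              compute_class_frequencies, discriminability,
                              lgf_features, word_weights)


def brute_force_tf(posts, lexicon, categories=CATEGORIES):
    """Independent nested-loop counter over raw token lists."""
    class_ids = lexicon.semantic_class_ids()
    tf = np.zeros((len(class_ids), len(categories)))
    for ci, cid in enumerate(class_ids):
        for cj, cat in enumerate(categories):
            matches, total = 0, 0
            for post in posts:
                if post.label != cat:
                    continue
                for tok in post.tokens[:post.true_length]:
                    total += 1
                    hit = False
                    for pattern, ids in lexicon.entries.items():
                        if cid not in ids:
                            continue
                        if pattern.endswith("*"):
                            if tok.startswith(pattern[:-1]):
                                hit = True
                        elif tok == pattern:
                            hit = True
                    if hit:
                        matches += 1
            tf[ci, cj] = matches / total if total else 0.0
    return tf


class TestClassFrequencies:
    def test_hand_counted_example(self, tiny_lexicon):
        posts = [make_post(["die", "b", "c"], label="green"),
                 make_post(["friendly", "e"], label="green")]
        freq = compute_class_frequencies(posts, tiny_lexicon)
        assert freq.row(1)[CATEGORIES.index("green")] == pytest.approx(1 / 5)
        assert freq.row(2)[CATEGORIES.index("green")] == pytest.approx(1 / 5)

    def test_absent_class_is_zero_everywhere(self, tiny_lexicon):
        posts = [make_post(["x", "y"], label=c) for c in CATEGORIES]
        freq = compute_class_frequencies(posts, tiny_lexicon)
        assert np.all(freq.tf == 0)

    def test_saturated_category(self, tiny_lexicon):
        posts = [make_post(["die", "dying"], label="crisis"),
                 make_post(["x"], label="green")]
        freq = compute_class_frequencies(posts, tiny_lexicon)
        assert freq.row(1)[CATEGORIES.index("crisis")] == 1.0

    def test_pad_tokens_excluded(self, tiny_lexicon):
        posts = [make_post(["die"], n=10, label="crisis"),
                 make_post(["x"], label="green")]
        freq = compute_class_frequencies(posts, tiny_lexicon)
        assert freq.token_totals[CATEGORIES.index("crisis")] == 1
        assert freq.row(1)[CATEGORIES.index("crisis")] == 1.0

    def test_empty_corpus_rejected(self, tiny_lexicon):
        with pytest.raises(WeightingError):
            compute_class_frequencies([], tiny_lexicon)

    def test_matches_brute_force_on_random_corpora(self, rng):
        """Counting-oracle equivalence on 200 random (corpus, lexicon) pairs."""
        vocab = [f"w{i}" for i in range(12)]
        for _ in range(200):
            n_classes = int(rng.integers(1, 4))
            classes = {i: WordClass(i, f"c{i}") for i in range(1, n_classes + 1)}
            entries = {}
            for w in vocab:
                if rng.random() < 0.5:
                    pat = w[: int(rng.integers(1, 3))] + "*" \
                        if rng.random() < 0.3 else w
                    entries[pat] = entries.get(pat, frozenset()) | frozenset(
                        {int(rng.integers(1, n_classes + 1))})
            if not entries:
                entries = {vocab[0]: frozenset({1})}
            lexicon = Lexicon(classes=classes, entries=entries)
            posts = []
            for i in range(int(rng.integers(4, 10))):
                toks = [vocab[j] for j in
                        rng.integers(0, len(vocab), rng.integers(1, 8))]
                posts.append(make_post(toks, n=8,
                                       label=CATEGORIES[rng.integers(4)],
                                       post_id=f"p{i}"))
            freq = compute_class_frequencies(posts, lexicon)
            np.testing.assert_array_equal(freq.tf, brute_force_tf(posts, lexicon))

    def test_duplicating_posts_leaves_tf_unchanged(self, tiny_lexicon):
        posts = [make_post(["die", "b"], label="crisis"),
                 make_post(["friendx"], label="green")]
        f1 = compute_class_frequencies(posts, tiny_lexicon)
        f2 = compute_class_frequencies(posts + posts, tiny_lexicon)
        np.testing.assert_allclose(f1.tf, f2.tf)


def table(tf_rows, class_ids=None):
    tf = np.array(tf_rows, dtype=float)
    ids = class_ids or list(range(1, len(tf) + 1))
    return ClassFrequencyTable(CATEGORIES, ids, tf, np.ones(4))


class TestDiscriminability:
    def test_closed_form_chain(self):
        """TF' row (1.0, 0.5, 0.25, 0.25): mu = 0.5, delta = sqrt(0.375)."""
        disc = discriminability(table([[1.0, 0.5, 0.25, 0.25]]), k=1)
        assert disc.mu[0] == pytest.approx(0.5)
        assert disc.sd[0] == pytest.approx(math.sqrt(0.375))
        assert disc.sd[0] == pytest.approx(0.61237, abs=1e-5)

    def test_constant_row_has_zero_spread(self):
        disc = discriminability(table([[0.3, 0.3, 0.3, 0.3]]), k=1)
        np.testing.assert_allclose(disc.tf_norm[0], 1.0)
        assert disc.sd[0] == pytest.approx(0.0)

    def test_zero_row_stays_zero(self):
        disc = discriminability(table([[0, 0, 0, 0], [0.4, 0.1, 0.1, 0.1]]), k=2)
        assert np.all(disc.tf_norm[0] == 0) and disc.sd[0] == 0.0

    def test_top_k_selection_and_tie_break(self):
        # identical rows => identical delta; tie broken by ascending class id
        disc = discriminability(
            table([[0.4, 0.1, 0.1, 0.1], [0.4, 0.1, 0.1, 0.1],
                   [0.2, 0.2, 0.2, 0.2]]), k=1)
        assert disc.selected == [1]

    def test_top_k_orders_by_delta(self):
        disc = discriminability(
            table([[0.2, 0.2, 0.2, 0.2], [0.7, 0.1, 0.1, 0.1]]), k=1)
        assert disc.selected == [2]

    def test_normalized_peak_is_one(self, rng):
        tf = rng.random((6, 4)) + 0.01
        disc = discriminability(table(tf.tolist()), k=3)
        np.testing.assert_allclose(disc.tf_norm.max(axis=1), 1.0)

    def test_k_below_one_rejected(self):
        with pytest.raises(WeightingError):
            discriminability(table([[1, 0, 0, 0]]), k=0)


def lexicon_with_deltas():
    """Two selected classes with delta = (0.4, 0.3), via crafted TF rows.

    Row (1, b, b, b) gives delta = sqrt(3)*(1-b)/2... solved numerically
    instead: rows are chosen so delta comes out exactly 0.4 and 0.3 since
    delta = sqrt(sum (x - mu)^2) for row (1, b, b, b) equals (1-b)*sqrt(3)/2.
    """
    # (1-b)*sqrt(3)/2 = delta  =>  b = 1 - 2*delta/sqrt(3)
    b1 = 1 - 2 * 0.4 / math.sqrt(3)
    b2 = 1 - 2 * 0.3 / math.sqrt(3)
    lex = Lexicon(
        classes={1: WordClass(1, "a"), 2: WordClass(2, "b"),
                 3: WordClass(3, "unselected")},
        entries={"high": frozenset({1}), "low": frozenset({2}),
                 "both": frozenset({1, 2}), "out": frozenset({3})},
    )
    tf = table([[1, b1, b1, b1], [1, b2, b2, b2], [0.1, 0.1, 0.1, 0.1]],
               class_ids=[1, 2, 3])
    disc = discriminability(tf, k=2)
    assert disc.selected == [1, 2]
    np.testing.assert_allclose(sorted(disc.sd[:2], reverse=True), [0.4, 0.3],
                               atol=1e-12)
    return lex, disc


class TestWordWeights:
    def test_out_of_lexicon_weight_is_exactly_one(self):
        lex, disc = lexicon_with_deltas()
        assert word_weights(lex, disc).weight("zzz") == 1.0

    def test_unselected_class_token_weight_is_one(self):
        lex, disc = lexicon_with_deltas()
        assert word_weights(lex, disc).weight("out") == 1.0

    def test_softmax_share_value(self):
        """delta = (0.4, 0.3): in-class weight = e^0.4/(e^0.4+e^0.3)+1."""
        lex, disc = lexicon_with_deltas()
        expected = math.exp(0.4) / (math.exp(0.4) + math.exp(0.3)) + 1
        assert word_weights(lex, disc).weight("high") == pytest.approx(expected)
        assert word_weights(lex, disc).weight("high") == pytest.approx(1.52498,
                                                                       abs=1e-5)

    def test_multi_class_token_uses_max_delta(self):
        lex, disc = lexicon_with_deltas()
        wt = word_weights(lex, disc)
        assert wt.weight("both") == pytest.approx(wt.weight("high"))

    def test_weight_bounds(self, rng):
        """1 <= a < 2 always; a = 1 iff no selected class matches."""
        lex, disc = lexicon_with_deltas()
        wt = word_weights(lex, disc)
        for tok in ["high", "low", "both", "out", "zzz", "PAD", "URL"]:
            a = wt.weight(tok)
            assert 1.0 <= a < 2.0
            in_selected = bool(lex.match(tok) & set(disc.selected))
            assert (a == 1.0) == (not in_selected)

    def test_empty_selection_rejected(self):
        lex, disc = lexicon_with_deltas()
        disc.selected = []
        with pytest.raises(WeightingError):
            word_weights(lex, disc)


class TestLGF:
    def test_quarter_fraction(self, tiny_lexicon):
        freq = compute_class_frequencies(
            [make_post(["die", "a", "b", "c"], label="crisis"),
             make_post(["x"], label="green")], tiny_lexicon)
        disc = discriminability(freq, k=2)
        post = make_post(["die", "a", "b", "c"])
        vec = lgf_features(post, tiny_lexicon, disc)
        assert vec[disc.selected.index(1)] == pytest.approx(0.25)

    def test_no_match_is_zero_vector(self, tiny_lexicon):
        freq = compute_class_frequencies(
            [make_post(["die"], label=c) for c in CATEGORIES], tiny_lexicon)
        disc = discriminability(freq, k=2)
        assert np.all(lgf_features(make_post(["q", "r"]), tiny_lexicon, disc) == 0)

    def test_saturated_post(self, tiny_lexicon):
        freq = compute_class_frequencies(
            [make_post(["die"], label=c) for c in CATEGORIES], tiny_lexicon)
        disc = discriminability(freq, k=2)
        vec = lgf_features(make_post(["die", "dying"]), tiny_lexicon, disc)
        assert vec[disc.selected.index(1)] == pytest.approx(1.0)

    def test_empty_post_is_zero_vector(self, tiny_lexicon):
        freq = compute_class_frequencies(
            [make_post(["die"], label=c) for c in CATEGORIES], tiny_lexicon)
        disc = discriminability(freq, k=1)
        vec = lgf_features(make_post([], n=3), tiny_lexicon, disc)
        assert np.all(vec == 0)
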