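"""Synthetic lexicons and labeled corpora with planted lexical signal.

Real triage corpora and the proprietary lexicon cannot be redistributed, so
this module generates both with known ground truth: a lexicon of synthetic
word classes and a bag-of-words corpus whose class-conditional token-emission
rates, per-category emoji inventories and link insertions are fully
specified.  Planting one word class with strongly category-dependent rates
(high in crisis posts, near zero in green) gives an analytically known
discriminability ranking and makes the four categories learnable, so the
whole pipeline — frequency counting, class ranking, attention weighting and
classification — can be validated end to end.

Token emissions are i.i.d. given the category.  That is deliberate: it is
sufficient to exercise every pipeline stage, though it reproduces none of
the sequential structure of real posts (see the methods note for what this
does and does not demonstrate).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from lexcnn.lexicon import Lexicon, WordClass
from lexcnn.preprocess import CATEGORIES, RawPost


class GenerationError(ValueError):
    pass


DEFAULT_EMOJI_INVENTORY: tuple[str, ...] = ("😢", "😭", "💔", "😀", "😊", "🙂")

# Per-category per-emoji insertion probabilities (CATEGORIES order:
# crisis, red, amber, green).  The first three emojis are urgent-only, the
# next two non-urgent-only, the last appears everywhere (hence ends up
# neutral).  Each emoji is inserted Binomial(emoji_reps, p) times, so the
# categories differ in the *count* of same-polarity emojis — necessary
# because preprocessing collapses emojis to three polarity markers, after
# which crisis vs red (and green vs amber) can only differ in marker counts.
# Rates are chosen so the collapsed features keep the four categories
# Bayes-separable to ~0.92 at the default post length; see the methods note.
DEFAULT_EMOJI_RATES: dict[str, tuple[float, ...]] = {
    "crisis": (0.75, 0.75, 0.75, 0.00, 0.00, 0.10),
    "red":    (0.15, 0.15, 0.15, 0.00, 0.00, 0.10),
    "amber":  (0.00, 0.00, 0.00, 0.15, 0.15, 0.10),
    "green":  (0.00, 0.00, 0.00, 0.75, 0.75, 0.10),
}

_SUFFIXES = ("s", "ed", "ing")


@dataclass
class GeneratorSpec:
    num_classes: int = 8
    words_per_class: int = 10
    background_vocab: int = 200
    rates: dict[str, list[float]] = field(default_factory=dict)
    # per category: length-num_classes emission probabilities
    post_length_mean: int = 30
    post_length_min: int = 10
    post_length_max: int = 60
    posts_per_category: int = 400
    emoji_inventory: tuple[str, ...] = DEFAULT_EMOJI_INVENTORY
    emoji_rates: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_EMOJI_RATES))
    emoji_reps: int = 3
    url_rate: float = 0.1
    wildcard_fraction: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        for name in ("num_classes", "words_per_class", "background_vocab",
                     "posts_per_category", "post_length_mean",
                     "post_length_min", "post_length_max"):
            if getattr(self, name) <= 0:
                raise GenerationError(f"{name} must be positive")
        if self.post_length_min > self.post_length_max:
            raise GenerationError("post_length_min exceeds post_length_max")
        if not (0 <= self.url_rate <= 1 and 0 <= self.wildcard_fraction <= 1):
            raise GenerationError("url_rate and wildcard_fraction must be in [0, 1]")
        if self.emoji_reps < 1:
            raise GenerationError("emoji_reps must be >= 1")
        for cat in CATEGORIES:
            if cat not in self.rates:
                raise GenerationError(f"missing emission rates for category {cat!r}")
            r = self.rates[cat]
            if len(r) != self.num_classes:
                raise GenerationError(
                    f"category {cat!r}: expected {self.num_classes} rates, got {len(r)}")
            if any(x < 0 for x in r) or sum(r) > 1:
                raise GenerationError(
                    f"category {cat!r}: rates must be >= 0 and sum to <= 1")
            er = self.emoji_rates.get(cat)
            if er is None or len(er) != len(self.emoji_inventory):
                raise GenerationError(f"category {cat!r}: bad emoji rates")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["emoji_inventory"] = list(self.emoji_inventory)
        d["emoji_rates"] = {c: list(v) for c, v in self.emoji_rates.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorSpec":
        d = dict(d)
        if "emoji_inventory" in d:
            d["emoji_inventory"] = tuple(d["emoji_inventory"])
        if "emoji_rates" in d:
            d["emoji_rates"] = {c: tuple(v) for c, v in d["emoji_rates"].items()}
        spec = cls(**d)
        spec.validate()
        return spec


def planted_signal_spec() -> GeneratorSpec:
    """The default study-condition fixture: one strongly planted word class.

    Class 1 is emitted at rates (crisis 0.08, red 0.05, amber 0.02,
    green 0.005); the other seven classes at a uniform 0.02 in every
    category, so only the planted class discriminates.  Evaluating the
    normalized-rate spread on the true rates gives the planted class
    delta ~= 0.80 while uniform classes have delta 0 in expectation.
    """
    spec = GeneratorSpec(
        rates={
            "crisis": [0.08] + [0.02] * 7,
            "red":    [0.05] + [0.02] * 7,
            "amber":  [0.02] + [0.02] * 7,
            "green":  [0.005] + [0.02] * 7,
        },
    )
    spec.validate()
    return spec


def generate_lexicon(spec: GeneratorSpec, seed: int) -> Lexicon:
    """Synthetic lexicon: ``num_classes`` classes of unique tokens.

    A ``wildcard_fraction`` share of entries are emitted as trailing-wildcard
    patterns; the corpus generator occasionally inflects those words so the
    wildcard matching path is exercised.  Class vocabularies are disjoint
    from each other and from the background vocabulary by construction.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    classes: dict[int, WordClass] = {}
    entries: dict[str, frozenset[int]] = {}
    for cid in range(1, spec.num_classes + 1):
        classes[cid] = WordClass(cid, f"class_{cid:02d}")
        for w in range(spec.words_per_class):
            word = f"c{cid:02d}w{w:02d}x"
            pattern = word + "*" if rng.random() < spec.wildcard_fraction else word
            if pattern in entries:
                raise GenerationError("vocabulary exhaustion: duplicate pattern")
            entries[pattern] = frozenset({cid})
    return Lexicon(classes=classes, entries=entries)


def _class_words(lexicon: Lexicon) -> dict[int, list[tuple[str, bool]]]:
    words: dict[int, list[tuple[str, bool]]] = {cid: [] for cid in lexicon.classes}
    for pattern, ids in sorted(lexicon.entries.items()):
        base = pattern.rstrip("*")
        wildcard = pattern.endswith("*")
        for cid in ids:
            words[cid].append((base, wildcard))
    return words


def generate_corpus(spec: GeneratorSpec, lexicon: Lexicon,
                    seed: int) -> list[RawPost]:
    """Labeled posts: per category, ``posts_per_category`` bag-of-words posts.

    Each token is drawn independently: with probability ``rates[c][i]`` from
    class i's word list (wildcard words are inflected with probability 0.3),
    otherwise from the background vocabulary.  Emojis are appended per the
    per-category emission probabilities and a link is inserted with
    probability ``url_rate``.
    """
    spec.validate()
    class_ids = sorted(lexicon.classes)
    if len(class_ids) != spec.num_classes:
        raise GenerationError("lexicon class count does not match the spec")
    words = _class_words(lexicon)
    rng = np.random.default_rng(seed)
    posts: list[RawPost] = []
    sigma = max(1.0, spec.post_length_mean / 4)
    for cat in CATEGORIES:
        rates = np.array(spec.rates[cat])
        cum = np.cumsum(rates)
        for i in range(spec.posts_per_category):
            length = int(np.clip(round(rng.normal(spec.post_length_mean, sigma)),
                                 spec.post_length_min, spec.post_length_max))
            toks: list[str] = []
            for _ in range(length):
                u = rng.random()
                j = int(np.searchsorted(cum, u, side="right"))
                if j < len(class_ids):
                    base, wildcard = words[class_ids[j]][
                        rng.integers(len(words[class_ids[j]]))]
                    if wildcard and rng.random() < 0.3:
                        base += _SUFFIXES[rng.integers(len(_SUFFIXES))]
                    toks.append(base)
                else:
                    toks.append(f"bg{rng.integers(spec.background_vocab):03d}")
            if rng.random() < spec.url_rate:
                pos = int(rng.integers(len(toks) + 1))
                toks.insert(pos, f"https://example.com/p{rng.integers(10_000)}")
            for emo, p in zip(spec.emoji_inventory, spec.emoji_rates[cat]):
                toks.extend([emo] * int(rng.binomial(spec.emoji_reps, p)))
            if toks and rng.random() < 0.5:
                toks[0] = toks[0].capitalize()
            posts.append(RawPost(f"{cat}_{i:04d}", " ".join(toks), cat))
    return posts


def write_ground_truth(spec: GeneratorSpec, lexicon: Lexicon, path) -> None:
    """Generator parameters + class vocabularies, for oracle tests."""
    truth = {
        "spec": spec.to_dict(),
        "categories": list(CATEGORIES),
        "class_words": {str(cid): sorted(p for p, ids in lexicon.entries.items()
                                         if cid in ids)
                        for cid in sorted(lexicon.classes)},
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(truth, fh, indent=2, ensure_ascii=False)
        fh.write("\n")
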