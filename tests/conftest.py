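import numpy as np
import pytest

from lexcnn.lexicon import Lexicon, WordClass
from lexcnn.preprocess import TokenizedPost, PAD


@pytest.fixture
def tiny_lexicon() -> Lexicon:
    """Two-class lexicon with a literal, a wildcard and a shared entry."""
    return Lexicon(
        classes={1: WordClass(1, "death_c"), 2: WordClass(2, "friends_c")},
        entries={
            "die": frozenset({1}),
            "dying": frozenset({1}),
            "friend*": frozenset({2}),
            "mourn": frozenset({1, 2}),
        },
    )


def make_post(tokens: list[str], n: int | None = None, label: str | None = None,
              post_id: str = "p") -> TokenizedPost:
    n = n if n is not None else len(tokens)
    true_length = min(len(tokens), n)
    padded = tokens[:n] + [PAD] * max(0, n - len(tokens))
    return TokenizedPost(post_id=post_id, tokens=padded,
                         true_length=true_length, label=label)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
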