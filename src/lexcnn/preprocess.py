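"""Raw posts -> padded token sequences.

Pipeline order: link replacement -> emoji polarity substitution -> character
filtering -> tokenization -> padding/truncation.  Stop words are deliberately
retained: their distribution differs across triage categories (e.g. negations
are over-represented in crisis posts) and removing them would discard signal.

Emoji polarity is corpus-driven: an emoji seen only in urgent posts
(red/crisis) is negative, only in non-urgent posts (green/amber) positive, in
both neutral.  Each polarity is then injected into the text as one of the
reserved marker tokens EMO_NEG / EMO_POS / EMO_NEU, which the downstream
vocabulary treats as ordinary tokens (they match no lexicon class).
"""

from __future__ import annotations

import json
import re
import string
from dataclasses import dataclass
from typing import Iterable

CATEGORIES: tuple[str, ...] = ("crisis", "red", "amber", "green")
URGENT: frozenset[str] = frozenset({"crisis", "red"})
NON_URGENT: frozenset[str] = frozenset({"green", "amber"})

PAD = "PAD"
URL = "URL"
EMO_NEG = "EMO_NEG"
EMO_POS = "EMO_POS"
EMO_NEU = "EMO_NEU"
UNK = "UNK"
RESERVED_TOKENS: tuple[str, ...] = (PAD, URL, EMO_NEG, EMO_POS, EMO_NEU, UNK)

_LINK_RE = re.compile(r"(?:https?://|www\.)\S+", re.IGNORECASE)

# Unicode emoji blocks (BMP symbols + supplementary emoji planes).
_EMOJI_RANGES = (
    (0x1F300, 0x1FAFF),
    (0x2600, 0x27BF),
    (0x1F000, 0x1F0FF),
    (0x2190, 0x21FF),  # arrows, occasionally used emotively
    (0xFE00, 0xFE0F),  # variation selectors travelling with emojis
)

DEFAULT_ASCII_EMOTICONS: tuple[str, ...] = (
    ":)", ":(", ":-)", ":-(", ":D", ":'(", ";)", ":/", "<3", "xD",
)


class PreprocessError(ValueError):
    pass


@dataclass
class RawPost:
    post_id: str
    text: str
    label: str | None = None

    def __post_init__(self) -> None:
        if not self.post_id:
            raise PreprocessError("post_id must be non-empty")
        if self.label is not None and self.label not in CATEGORIES:
            raise PreprocessError(
                f"label {self.label!r} not one of {CATEGORIES}"
            )


@dataclass
class TokenizedPost:
    post_id: str
    tokens: list[str]
    true_length: int
    label: str | None = None

    def __post_init__(self) -> None:
        if self.true_length > len(self.tokens):
            raise PreprocessError("true_length exceeds padded length")


def replace_links(text: str) -> str:
    """Replace every http/https/www link with the single token ``URL``."""
    return _LINK_RE.sub(URL, text)


def _is_emoji_char(ch: str) -> bool:
    cp = ord(ch)
    return any(lo <= cp <= hi for lo, hi in _EMOJI_RANGES)


def find_emojis(text: str,
                emoticons: Iterable[str] = DEFAULT_ASCII_EMOTICONS) -> list[str]:
    """All emoji occurrences in a text: Unicode emoji chars + ASCII emoticons."""
    found = [ch for ch in text if _is_emoji_char(ch)]
    for emo in emoticons:
        found.extend([emo] * text.count(emo))
    return found


def assign_emoji_polarity(corpus: Iterable[RawPost],
                          emoticons: Iterable[str] = DEFAULT_ASCII_EMOTICONS,
                          ) -> dict[str, str]:
    """Map each emoji observed in a labeled corpus to negative/positive/neutral.

    Urgent-only emojis (crisis/red posts) are negative, non-urgent-only
    (green/amber) positive, and emojis seen in both groups neutral.
    Links are replaced first so URL punctuation (``:/``) is never mistaken
    for an emoticon.
    """
    emoticons = tuple(emoticons)
    seen_urgent: set[str] = set()
    seen_calm: set[str] = set()
    n_labeled = 0
    for post in corpus:
        if post.label is None:
            continue
        n_labeled += 1
        emojis = find_emojis(replace_links(post.text), emoticons)
        if post.label in URGENT:
            seen_urgent.update(emojis)
        else:
            seen_calm.update(emojis)
    if n_labeled == 0:
        raise PreprocessError("emoji polarity needs at least one labeled post")
    polarity: dict[str, str] = {}
    for emo in seen_urgent | seen_calm:
        if emo in seen_urgent and emo in seen_calm:
            polarity[emo] = "neutral"
        elif emo in seen_urgent:
            polarity[emo] = "negative"
        else:
            polarity[emo] = "positive"
    return polarity


_POLARITY_MARKER = {"negative": EMO_NEG, "positive": EMO_POS, "neutral": EMO_NEU}


def substitute_emojis(text: str, polarity_map: dict[str, str]) -> str:
    """Replace mapped emojis with their polarity marker token (space-padded)."""
    # Longest first so multi-char emoticons win over their prefixes.
    for emo in sorted(polarity_map, key=len, reverse=True):
        marker = f" {_POLARITY_MARKER[polarity_map[emo]]} "
        text = text.replace(emo, marker)
    return text


_KEEP = set(string.ascii_letters + string.digits + string.punctuation + string.whitespace)


def filter_chars(text: str) -> str:
    """Drop every character that is not ASCII letter/digit/punctuation/whitespace.

    Run after emoji substitution, so unmapped emojis and other undecodable
    symbols vanish while the ASCII marker tokens survive.
    """
    return "".join(ch for ch in text if ch in _KEEP)


_PUNCT_RE = re.compile(r"([%s])" % re.escape(string.punctuation))


def tokenize(text: str) -> list[str]:
    """Lowercasing whitespace tokenization with punctuation split out.

    Reserved marker tokens are kept verbatim (not lowercased, not split).
    """
    out: list[str] = []
    for chunk in text.split():
        if chunk in RESERVED_TOKENS:
            out.append(chunk)
            continue
        for tok in _PUNCT_RE.sub(r" \1 ", chunk).split():
            out.append(tok if tok in RESERVED_TOKENS else tok.lower())
    return out


def tokenize_and_pad(text: str, n: int,
                     polarity_map: dict[str, str] | None = None) -> TokenizedPost:
    """Tokenize a (link-replaced) text and pad/truncate to exactly ``n`` tokens.

    Emojis present in ``polarity_map`` are substituted by their marker before
    character filtering.  ``true_length`` is the pre-padding token count,
    capped at ``n``.
    """
    if n < 1:
        raise PreprocessError(f"sequence length n must be >= 1, got {n}")
    if polarity_map:
        text = substitute_emojis(text, polarity_map)
    tokens = tokenize(filter_chars(text))
    true_length = min(len(tokens), n)
    tokens = tokens[:n] + [PAD] * max(0, n - len(tokens))
    return TokenizedPost(post_id="", tokens=tokens, true_length=true_length)


def preprocess_post(post: RawPost, n: int,
                    polarity_map: dict[str, str] | None = None) -> TokenizedPost:
    tp = tokenize_and_pad(replace_links(post.text), n, polarity_map)
    tp.post_id = post.post_id
    tp.label = post.label
    return tp


def preprocess_corpus(corpus: list[RawPost], n: int,
                      polarity_map: dict[str, str] | None = None,
                      ) -> tuple[list[TokenizedPost], dict[str, str]]:
    """Full pipeline over a corpus; derives the polarity map if not supplied."""
    if polarity_map is None:
        polarity_map = assign_emoji_polarity(corpus)
    return [preprocess_post(p, n, polarity_map) for p in corpus], polarity_map


# ---------------------------------------------------------------- corpus I/O

def read_corpus(path) -> list[RawPost]:
    """Read a labeled corpus: JSONL ({"id","label","text"}) or 3-column TSV."""
    posts: list[RawPost] = []
    with open(path, encoding="utf-8") as fh:
        first = fh.read(1)
        fh.seek(0)
        if first == "{":
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    obj = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise PreprocessError(f"{path}: line {lineno}: {exc}") from None
                posts.append(RawPost(str(obj["id"]), obj["text"], obj.get("label")))
        else:
            for lineno, line in enumerate(fh, start=1):
                if not line.rstrip("\n"):
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) != 3:
                    raise PreprocessError(
                        f"{path}: line {lineno}: expected 3 tab-separated columns"
                    )
                pid, label, text = parts
                posts.append(RawPost(pid, text, label or None))
    ids = [p.post_id for p in posts]
    if len(set(ids)) != len(ids):
        raise PreprocessError(f"{path}: duplicate post ids")
    return posts


def write_corpus(corpus: Iterable[RawPost], path, fmt: str = "jsonl") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for post in corpus:
            if fmt == "jsonl":
                fh.write(json.dumps(
                    {"id": post.post_id, "label": post.label, "text": post.text},
                    ensure_ascii=False) + "\n")
            elif fmt == "tsv":
                if "\t" in post.text or "\n" in post.text:
                    raise PreprocessError("TSV cannot hold tabs/newlines in text")
                fh.write(f"{post.post_id}\t{post.label or ''}\t{post.text}\n")
            else:
                raise PreprocessError(f"unknown corpus format {fmt!r}")
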