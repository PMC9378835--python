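"""LIWC-style lexicon: word classes, word membership, wildcard matching.

The on-disk dialect is the tab-separated ``.dic`` interchange format used by
LIWC-compatible tools: a category header block delimited by ``%`` lines
(``id<TAB>name`` per line) followed by entry lines
``pattern<TAB>id[<TAB>id...]``.  Patterns are lowercase literal tokens or
trailing-wildcard prefixes such as ``friend*``; a wildcard entry matches any
token that begins with its prefix.  Class names ending in well-known
descriptive suffixes carry no semantics of their own; whether a class is
*semantic* (usable for discriminability weighting) is user-supplied metadata,
not inferred from the name.
"""

from __future__ import annotations

from dataclasses import dataclass, field


class LexiconError(ValueError):
    """Malformed or referentially inconsistent lexicon file."""


@dataclass(frozen=True)
class WordClass:
    class_id: int
    name: str
    semantic: bool = True


@dataclass
class Lexicon:
    """Word classes plus a pattern -> class_ids mapping.

    ``entries`` maps each pattern (literal token or trailing-``*`` prefix
    pattern) to the non-empty frozenset of class ids it belongs to.
    """

    classes: dict[int, WordClass]
    entries: dict[str, frozenset[int]]
    _exact: dict[str, frozenset[int]] = field(init=False, repr=False)
    _prefixes: list[tuple[str, frozenset[int]]] = field(init=False, repr=False)
    _cache: dict[str, frozenset[int]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.validate()
        object.__setattr__(self, "_exact", {})
        object.__setattr__(self, "_prefixes", [])
        for pattern, ids in self.entries.items():
            if pattern.endswith("*"):
                self._prefixes.append((pattern[:-1], ids))
            else:
                self._exact[pattern] = ids
        object.__setattr__(self, "_cache", {})

    def validate(self) -> None:
        if not self.classes:
            raise LexiconError("lexicon has no word classes")
        for pattern, ids in self.entries.items():
            if not ids:
                raise LexiconError(f"entry {pattern!r} maps to no class")
            if pattern != pattern.lower():
                raise LexiconError(f"entry {pattern!r} is not lowercase")
            if "*" in pattern[:-1]:
                raise LexiconError(
                    f"entry {pattern!r}: only a trailing '*' wildcard is supported"
                )
            unknown = ids - self.classes.keys()
            if unknown:
                raise LexiconError(
                    f"entry {pattern!r} references unknown class ids {sorted(unknown)}"
                )

    def semantic_class_ids(self) -> list[int]:
        """Ids of classes usable for frequency/discriminability analysis."""
        return sorted(c.class_id for c in self.classes.values() if c.semantic)

    def match(self, token: str) -> frozenset[int]:
        """Memoized :func:`match_token`."""
        hit = self._cache.get(token)
        if hit is None:
            hit = match_token(self, token)
            self._cache[token] = hit
        return hit


def match_token(lexicon: Lexicon, token: str) -> frozenset[int]:
    """Class ids of a lowercased token: exact entry plus matching wildcards.

    Returns the union over (a) the literal entry equal to ``token``, if any,
    and (b) every wildcard entry whose prefix is a prefix of ``token``.
    Out-of-lexicon tokens yield the empty set.
    """
    ids: set[int] = set(lexicon._exact.get(token, ()))
    for prefix, pids in lexicon._prefixes:
        if token.startswith(prefix):
            ids |= pids
    return frozenset(ids)


def load_lexicon(path) -> Lexicon:
    """Parse a ``.dic`` lexicon file (UTF-8).

    Raises :class:`LexiconError` naming the offending line for malformed
    headers, unknown class-id references, or an empty category block.
    """
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()

    stripped = [ln.strip() for ln in lines]
    if not stripped or stripped[0] != "%":
        raise LexiconError(f"{path}: line 1: expected '%' header delimiter")
    try:
        end = stripped.index("%", 1)
    except ValueError:
        raise LexiconError(f"{path}: unterminated '%' category header") from None

    classes: dict[int, WordClass] = {}
    for lineno, raw in enumerate(stripped[1:end], start=2):
        if not raw:
            continue
        parts = raw.split("\t")
        if len(parts) < 2:
            raise LexiconError(f"{path}: line {lineno}: malformed category line {raw!r}")
        try:
            cid = int(parts[0])
        except ValueError:
            raise LexiconError(
                f"{path}: line {lineno}: category id {parts[0]!r} is not an integer"
            ) from None
        if cid in classes:
            raise LexiconError(f"{path}: line {lineno}: duplicate class id {cid}")
        name = parts[1]
        semantic = True
        if len(parts) >= 3:
            semantic = parts[2].strip().lower() not in ("0", "false", "descriptive")
        classes[cid] = WordClass(cid, name, semantic)
    if not classes:
        raise LexiconError(f"{path}: empty category block")

    entries: dict[str, frozenset[int]] = {}
    for lineno, raw in enumerate(stripped[end + 1:], start=end + 2):
        if not raw:
            continue
        parts = raw.split("\t")
        if len(parts) < 2:
            raise LexiconError(f"{path}: line {lineno}: malformed entry line {raw!r}")
        pattern = parts[0].lower()
        try:
            ids = frozenset(int(p) for p in parts[1:] if p)
        except ValueError:
            raise LexiconError(
                f"{path}: line {lineno}: non-integer class id in entry {raw!r}"
            ) from None
        unknown = ids - classes.keys()
        if unknown:
            raise LexiconError(
                f"{path}: line {lineno}: entry {pattern!r} references unknown "
                f"class ids {sorted(unknown)}"
            )
        entries[pattern] = entries.get(pattern, frozenset()) | ids

    return Lexicon(classes=classes, entries=entries)


def write_lexicon(lexicon: Lexicon, path) -> None:
    """Write a lexicon in the same ``.dic`` dialect that :func:`load_lexicon` reads."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("%\n")
        for cid in sorted(lexicon.classes):
            cls = lexicon.classes[cid]
            flag = "" if cls.semantic else "\t0"
            fh.write(f"{cid}\t{cls.name}{flag}\n")
        fh.write("%\n")
        for pattern in sorted(lexicon.entries):
            ids = "\t".join(str(i) for i in sorted(lexicon.entries[pattern]))
            fh.write(f"{pattern}\t{ids}\n")
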