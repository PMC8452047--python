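"""Word-emotion lexicon readers.

Two dialects are supported:

* a dimensional lexicon mapping each word to real-valued valence, arousal
  and dominance scores in [0, 1] (``word<TAB>valence<TAB>arousal<TAB>dominance``);
* a categorical lexicon in long format associating words with eight basic
  emotions (anger, anticipation, disgust, fear, joy, sadness, surprise,
  trust) plus the two sentiment polarities (``word<TAB>emotion<TAB>flag``).

Dominance is parsed and retained for round-tripping but no downstream
metric uses it.  Lookups are case-normalized to lowercase; a missing word
is an explicit ``None``, never a default score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "CATEGORIES",
    "DimensionalLexicon",
    "CategoricalLexicon",
    "LexiconFormatError",
    "load_vad_lexicon",
    "load_emotion_lexicon",
]

#: The fixed category set of the categorical lexicon dialect.
CATEGORIES = frozenset(
    {
        "anger",
        "anticipation",
        "disgust",
        "fear",
        "joy",
        "sadness",
        "surprise",
        "trust",
        "negative",
        "positive",
    }
)


class LexiconFormatError(ValueError):
    """A lexicon file violates its dialect (bad column count, label, range ...)."""


@dataclass
class DimensionalLexicon:
    """Word -> (valence, arousal, dominance) scores, each in [0, 1].

    ``source`` records where the lexicon came from (opaque version
    metadata); ``n_duplicates`` counts input rows dropped because an
    earlier row already defined the word.
    """

    entries: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    source: str | None = None
    n_duplicates: int = 0

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, word: str) -> bool:
        return word.lower() in self.entries

    def get(self, word: str) -> tuple[float, float] | None:
        """Return ``(valence, arousal)`` for ``word`` or ``None`` if absent."""
        entry = self.entries.get(word.lower())
        if entry is None:
            return None
        return (entry[0], entry[1])

    def coverage(self, tokens: Iterable[str]) -> float:
        """Fraction of ``tokens`` (with multiplicity) that have an entry."""
        tokens = list(tokens)
        if not tokens:
            return 0.0
        hits = sum(1 for t in tokens if t.lower() in self.entries)
        return hits / len(tokens)

    def remove_words(self, words: Iterable[str]) -> int:
        """Delete entries (e.g. domain-inappropriate ones); returns #removed."""
        removed = 0
        for w in words:
            if self.entries.pop(w.lower(), None) is not None:
                removed += 1
        return removed

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for word, (v, a, d) in self.entries.items():
                fh.write(f"{word}\t{v!r}\t{a!r}\t{d!r}\n")


@dataclass
class CategoricalLexicon:
    """Word -> subset of :data:`CATEGORIES` (binary associations)."""

    entries: dict[str, frozenset[str]] = field(default_factory=dict)
    source: str | None = None

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, word: str) -> bool:
        return word.lower() in self.entries

    def categories(self, word: str) -> frozenset[str] | None:
        """Category set for ``word`` (possibly empty), or ``None`` if uncovered."""
        return self.entries.get(word.lower())

    def has_category(self, word: str, category: str) -> bool:
        cats = self.entries.get(word.lower())
        return cats is not None and category in cats

    def coverage(self, tokens: Iterable[str]) -> float:
        tokens = list(tokens)
        if not tokens:
            return 0.0
        hits = sum(1 for t in tokens if t.lower() in self.entries)
        return hits / len(tokens)

    def remove_words(self, words: Iterable[str]) -> int:
        removed = 0
        for w in words:
            if self.entries.pop(w.lower(), None) is not None:
                removed += 1
        return removed

    def to_tsv(self, path: str | Path) -> None:
        cats = sorted(CATEGORIES)
        with open(path, "w", encoding="utf-8") as fh:
            for word, flags in self.entries.items():
                for c in cats:
                    fh.write(f"{word}\t{c}\t{1 if c in flags else 0}\n")


def _split_row(line: str) -> list[str]:
    return line.rstrip("\n").rstrip("\r").split("\t")


def _looks_like_header(fields: list[str]) -> bool:
    """A first row whose numeric columns fail to parse is treated as a header."""
    for f in fields[1:]:
        try:
            float(f)
        except ValueError:
            return True
    return False


def load_vad_lexicon(path: str | Path) -> DimensionalLexicon:
    """Read a dimensional lexicon TSV (word, valence, arousal, dominance).

    A header row is auto-detected.  Duplicate words keep the first
    occurrence (a warning reports the count).  Scores outside [0, 1] or
    unparsable numerics raise :class:`LexiconFormatError` naming the line.
    """
    path = Path(path)
    entries: dict[str, tuple[float, float, float]] = {}
    duplicates = 0
    with open(path, encoding="utf-8") as fh:
        lines = fh.readlines()
    start = 0
    if lines:
        first = _split_row(lines[0])
        if len(first) >= 4 and _looks_like_header(first[:4]):
            start = 1
    for lineno, line in enumerate(lines[start:], start=start + 1):
        if not line.strip():
            continue
        fields = _split_row(line)
        if len(fields) < 4:
            raise LexiconFormatError(
                f"{path}:{lineno}: expected 4 tab-separated columns, got {len(fields)}"
            )
        word = fields[0].strip().lower()
        try:
            v, a, d = (float(fields[1]), float(fields[2]), float(fields[3]))
        except ValueError as exc:
            raise LexiconFormatError(f"{path}:{lineno}: unparsable score: {exc}") from exc
        for name, score in (("valence", v), ("arousal", a), ("dominance", d)):
            if not 0.0 <= score <= 1.0:
                raise LexiconFormatError(
                    f"{path}:{lineno}: {name} score {score} outside [0, 1]"
                )
        if word in entries:
            duplicates += 1
            continue
        entries[word] = (v, a, d)
    if duplicates:
        warnings.warn(f"{path}: {duplicates} duplicate word(s) ignored (first kept)")
    if not entries:
        warnings.warn(f"{path}: empty dimensional lexicon")
    return DimensionalLexicon(entries=entries, source=str(path), n_duplicates=duplicates)


def load_emotion_lexicon(path: str | Path) -> CategoricalLexicon:
    """Read a categorical lexicon in long TSV format (word, emotion, 0/1 flag).

    A word whose rows are all zero-flagged is still *covered* (empty
    category set).  Unknown emotion labels and non-binary flags raise
    :class:`LexiconFormatError` naming the line.
    """
    path = Path(path)
    sets: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        lines = fh.readlines()
    start = 0
    if lines:
        first = _split_row(lines[0])
        if len(first) >= 3 and first[1].strip().lower() not in CATEGORIES:
            try:
                int(first[2])
            except ValueError:
                start = 1
    for lineno, line in enumerate(lines[start:], start=start + 1):
        if not line.strip():
            continue
        fields = _split_row(line)
        if len(fields) < 3:
            raise LexiconFormatError(
                f"{path}:{lineno}: expected 3 tab-separated columns, got {len(fields)}"
            )
        word = fields[0].strip().lower()
        label = fields[1].strip().lower()
        if label not in CATEGORIES:
            raise LexiconFormatError(f"{path}:{lineno}: unknown emotion label {label!r}")
        try:
            flag = int(fields[2])
        except ValueError as exc:
            raise LexiconFormatError(f"{path}:{lineno}: non-integer flag: {exc}") from exc
        if flag not in (0, 1):
            raise LexiconFormatError(f"{path}:{lineno}: flag must be 0 or 1, got {flag}")
        sets.setdefault(word, set())
        if flag:
            sets[word].add(label)
    if not sets:
        warnings.warn(f"{path}: empty categorical lexicon")
    return CategoricalLexicon(
        entries={w: frozenset(s) for w, s in sets.items()}, source=str(path)
    )
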