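"""Turn-structured dialogue ingestion.

A *turn* is a maximal run of uninterrupted utterances by one speaker:
consecutive transcript records with the same speaker are merged.  Speakers
with at least ``min_turns`` turns in a movie are its *main characters*; a
:class:`CharacterNarrative` lays one speaker's lemmas on the movie-global
word axis so trajectories of different characters are comparable.

Input dialects: TSV (``movie_id<TAB>turn_order<TAB>speaker<TAB>text``) and
JSON-Lines (one object per record with those keys).  Screenplay scraping,
slugline parsing and speaker aliasing are out of scope: the reader expects
dialogue records only.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

__all__ = [
    "Turn",
    "CharacterNarrative",
    "TranscriptError",
    "read_transcript",
    "tokenize",
    "select_main_characters",
    "build_narratives",
]

# word characters except underscore; apostrophes and punctuation split tokens
_TOKEN_RE = re.compile(r"[^\W_]+", re.UNICODE)


class TranscriptError(ValueError):
    """A transcript record is malformed or the file is unusable."""


@dataclass
class Turn:
    """One maximal uninterrupted run of utterances by a speaker."""

    movie_id: str
    turn_index: int  # 0-based, movie-global
    speaker: str
    text: str
    tokens: list[str] = field(default_factory=list)


@dataclass
class CharacterNarrative:
    """One speaker's lemmas in temporal order with movie-global positions.

    ``positions[i]`` is the movie-global word position of ``tokens[i]``
    (0-based over every token of the movie in turn order); the
    within-speaker ordinal is simply ``i``.
    """

    movie_id: str
    speaker: str
    tokens: list[str]
    positions: list[int]
    n_turns: int
    movie_total_tokens: int

    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def empty(self) -> bool:
        return len(self.tokens) == 0


def tokenize(text: str, lemmatizer: Callable[[str], str] | None = None) -> list[str]:
    """Lowercase, strip punctuation, split on non-word boundaries, lemmatize.

    Apostrophes split words into separate fragments ("I'm" -> ``i``, ``m``)
    and 1-character fragments are retained; lexicon lookup simply misses
    non-words.  ``lemmatizer`` is a pluggable ``str -> str`` normalizer
    (default: identity).
    """
    tokens = _TOKEN_RE.findall(text.lower())
    if lemmatizer is not None:
        tokens = [lemmatizer(t) for t in tokens]
    return tokens


def _iter_records(path: Path, dialect: str):
    """Yield (record_number, movie_id, order_key, speaker, text)."""
    with open(path, encoding="utf-8") as fh:
        lines = fh.readlines()
    if not any(line.strip() for line in lines):
        raise TranscriptError(f"{path}: empty transcript file")
    if dialect == "tsv":
        for recno, line in enumerate(lines, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").rstrip("\r").split("\t")
            if len(fields) < 4:
                raise TranscriptError(
                    f"{path}: record {recno}: expected 4 columns "
                    f"(movie_id, turn_order, speaker, text), got {len(fields)}"
                )
            movie_id, order, speaker, text = fields[0], fields[1], fields[2], fields[3]
            if not movie_id or not speaker:
                missing = "movie_id" if not movie_id else "speaker"
                raise TranscriptError(f"{path}: record {recno}: missing {missing}")
            try:
                order_key = float(order)
            except ValueError as exc:
                raise TranscriptError(
                    f"{path}: record {recno}: non-numeric turn_order {order!r}"
                ) from exc
            yield recno, movie_id, order_key, speaker, text
    elif dialect == "jsonl":
        for recno, line in enumerate(lines, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise TranscriptError(f"{path}: record {recno}: invalid JSON: {exc}") from exc
            for key in ("movie_id", "turn_order", "speaker", "text"):
                if key not in obj or obj[key] is None or obj[key] == "":
                    if key == "text" and obj.get(key) == "":
                        continue  # empty utterances are legal
                    raise TranscriptError(f"{path}: record {recno}: missing {key}")
            yield recno, str(obj["movie_id"]), float(obj["turn_order"]), str(
                obj["speaker"]
            ), str(obj["text"])
    else:
        raise ValueError(f"unknown dialect {dialect!r}; use 'tsv' or 'jsonl'")


def read_transcript(
    path: str | Path,
    dialect: str = "tsv",
    lemmatizer: Callable[[str], str] | None = None,
) -> dict[str, list[Turn]]:
    """Read a transcript and merge consecutive same-speaker records into turns.

    Returns ``{movie_id: [Turn, ...]}`` with turn order preserved (records
    are sorted by their order key within each movie).  Texts of merged
    records are concatenated with a single space; turns are tokenized.
    """
    path = Path(path)
    by_movie: dict[str, list[tuple[float, int, str, str]]] = {}
    for recno, movie_id, order_key, speaker, text in _iter_records(path, dialect):
        by_movie.setdefault(movie_id, []).append((order_key, recno, speaker, text))

    out: dict[str, list[Turn]] = {}
    for movie_id, records in by_movie.items():
        records.sort(key=lambda r: (r[0], r[1]))
        turns: list[Turn] = []
        for _, _, speaker, text in records:
            if turns and turns[-1].speaker == speaker:
                turns[-1].text = (turns[-1].text + " " + text).strip()
            else:
                turns.append(
                    Turn(movie_id=movie_id, turn_index=len(turns), speaker=speaker, text=text)
                )
        for t in turns:
            t.tokens = tokenize(t.text, lemmatizer)
        out[movie_id] = turns
    return out


def select_main_characters(turns: Sequence[Turn], min_turns: int = 50) -> set[str]:
    """Speakers with at least ``min_turns`` turns (boundary inclusive)."""
    if min_turns < 1:
        raise ValueError("min_turns must be >= 1")
    counts: dict[str, int] = {}
    for t in turns:
        counts[t.speaker] = counts.get(t.speaker, 0) + 1
    return {s for s, c in counts.items() if c >= min_turns}


def build_narratives(
    turns: Sequence[Turn], selected: Iterable[str]
) -> list[CharacterNarrative]:
    """One narrative per selected speaker, on the movie-global word axis.

    Global positions enumerate every token of the movie in turn order;
    speakers whose tokenized turns are empty yield an empty narrative with
    a warning.
    """
    selected = set(selected)
    position = 0
    per_speaker: dict[str, tuple[list[str], list[int]]] = {s: ([], []) for s in selected}
    turn_counts: dict[str, int] = {s: 0 for s in selected}
    movie_id = turns[0].movie_id if turns else ""
    for turn in turns:
        if turn.speaker in selected:
            turn_counts[turn.speaker] += 1
        for tok in turn.tokens:
            if turn.speaker in selected:
                per_speaker[turn.speaker][0].append(tok)
                per_speaker[turn.speaker][1].append(position)
            position += 1
    total = position
    narratives = []
    for speaker in sorted(selected):
        tokens, positions = per_speaker[speaker]
        if not tokens:
            warnings.warn(f"speaker {speaker!r} has no tokens after tokenization")
        narratives.append(
            CharacterNarrative(
                movie_id=movie_id,
                speaker=speaker,
                tokens=tokens,
                positions=positions,
                n_turns=turn_counts[speaker],
                movie_total_tokens=total,
            )
        )
    return narratives
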