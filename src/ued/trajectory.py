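"""Valence-arousal trajectories on normalized narrative time.

A speaker's emotional *location* at a point in their narrative is the
rolling mean of the valence and arousal scores of the lexicon-covered
("VAD") words they have just uttered.  Only full trailing windows are
used: point ``k`` averages scored words ``k .. k+window-1`` and is
anchored at the last word of its window, so the trajectory is causal and
has no inflated-variance partial windows at the start.

Normalized narrative time maps movie-global word position ``p`` to
``(p + 0.5) / movie_total_tokens``, placing a single-token movie at 0.5
rather than at a boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .lexicons import DimensionalLexicon
from .transcripts import CharacterNarrative

__all__ = [
    "ScoredWord",
    "TrajectoryPoint",
    "score_words",
    "rolling_trajectory",
    "normalized_time",
    "trajectory_va",
    "trajectory_times",
]


@dataclass
class ScoredWord:
    """One lexicon-covered word with its scores and coordinates."""

    token: str
    position: int  # movie-global word position
    ordinal: int  # 0-based over lexicon-covered words of this speaker
    valence: float
    arousal: float


@dataclass
class TrajectoryPoint:
    """Rolling-mean (v, a) location at trajectory index ``index``.

    ``position`` is the movie-global position of the window's last word;
    ``t`` is its normalized narrative time (``None`` when the movie total
    is unknown).
    """

    index: int
    position: int
    t: float | None
    v: float
    a: float


def score_words(
    narrative: CharacterNarrative, lexicon: DimensionalLexicon
) -> list[ScoredWord]:
    """Order-preserving filter of a narrative to lexicon-covered words.

    Words absent from the dimensional lexicon are dropped; the survivors
    get contiguous 0-based VAD ordinals.  ``len()`` of the result is the
    speaker's VAD word count.
    """
    scored: list[ScoredWord] = []
    for token, position in zip(narrative.tokens, narrative.positions):
        entry = lexicon.get(token)
        if entry is None:
            continue
        v, a = entry
        scored.append(
            ScoredWord(token=token, position=position, ordinal=len(scored), valence=v, arousal=a)
        )
    return scored


def normalized_time(position: int, movie_total_tokens: int) -> float:
    """Map a 0-based movie-global word position to narrative time in (0, 1)."""
    if movie_total_tokens <= 0:
        raise ValueError("movie_total_tokens must be positive")
    if not 0 <= position < movie_total_tokens:
        raise ValueError(
            f"position {position} outside [0, {movie_total_tokens})"
        )
    return (position + 0.5) / movie_total_tokens


def rolling_trajectory(
    scored: Sequence[ScoredWord],
    window: int = 10,
    movie_total_tokens: int | None = None,
) -> list[TrajectoryPoint]:
    """Full-window rolling mean of valence and arousal.

    Point ``k`` is the mean over scored words ``k .. k+window-1``,
    anchored at the window's last word's movie-global position.  Returns
    ``max(0, n - window + 1)`` points; a narrative shorter than the window
    yields an empty trajectory with a warning.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    n = len(scored)
    if n < window:
        warnings.warn(f"narrative too short for rolling window ({n} < {window})")
        return []
    v = np.array([w.valence for w in scored], dtype=float)
    a = np.array([w.arousal for w in scored], dtype=float)
    v_roll = sliding_window_view(v, window).mean(axis=1)
    a_roll = sliding_window_view(a, window).mean(axis=1)
    points = []
    for k in range(n - window + 1):
        pos = scored[k + window - 1].position
        t = (
            normalized_time(pos, movie_total_tokens)
            if movie_total_tokens is not None
            else None
        )
        points.append(TrajectoryPoint(index=k, position=pos, t=t, v=float(v_roll[k]), a=float(a_roll[k])))
    return points


def trajectory_va(points: Sequence[TrajectoryPoint]) -> np.ndarray:
    """Stack a trajectory into an ``(n, 2)`` array of (v, a) rows."""
    return np.array([[p.v, p.a] for p in points], dtype=float).reshape(-1, 2)


def trajectory_times(points: Sequence[TrajectoryPoint]) -> np.ndarray:
    """Normalized times of a trajectory (raises if any are unset)."""
    ts = [p.t for p in points]
    if any(t is None for t in ts):
        raise ValueError("trajectory points lack normalized time")
    return np.asarray(ts, dtype=float)
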