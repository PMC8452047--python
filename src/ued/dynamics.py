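"""Per-speaker utterance emotion dynamics metrics.

Six metric families summarize how a speaker's emotion word usage evolves:

1. *Emotion word density* — percentage of all uttered tokens associated
   with a category (denominator includes out-of-lexicon tokens); the
   dimensional analogue is the plain mean valence/arousal over
   lexicon-covered words.
2. *Home base* — 1-D confidence bands and the 2-D confidence ellipse of
   the rolling trajectory (see :mod:`ued.homebase`).
3. *Variability* — population-denominator SD per dimension; in 2-D, the
   mean of SD(v) and SD(a).
4. *Displacements* — completed excursions of the trajectory outside the
   home base, with exit/peak/return indices.
5. *Peak distance* — distance from the home-base perimeter to the
   excursion's farthest point.
6. *Rise / recovery rates* — peak distance divided by the number of words
   from exit to peak / peak to return (reactivity and regulation proxies).

Excursions that touch either end of the trajectory are *truncated*: they
are reported but excluded from all averages, and averages are withheld
entirely when fewer than ``min_displacements`` usable excursions exist.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .homebase import HomeBase1D, HomeBaseEllipse, contains, home_base_1d, home_base_2d, perimeter_distance
from .lexicons import CATEGORIES, CategoricalLexicon, DimensionalLexicon
from .trajectory import ScoredWord, TrajectoryPoint, rolling_trajectory, score_words, trajectory_va
from .transcripts import CharacterNarrative

__all__ = [
    "Displacement",
    "UEDProfile",
    "emotion_word_density",
    "dimensional_density",
    "variability",
    "variability_2d",
    "detect_displacements",
    "summarize_profile",
]


@dataclass
class Displacement:
    """One excursion of the trajectory outside the home base.

    Indices are trajectory-point indices (consecutive points differ by one
    VAD word, so index differences are word counts).  ``exit_index`` is
    the last inside point before the excursion, ``return_index`` the first
    inside point after it; both are ``None`` on the open side of a
    truncated excursion.
    """

    exit_index: int | None
    first_out_index: int
    peak_index: int
    return_index: int | None
    length: int  # number of outside trajectory points (VAD words)
    peak_distance: float
    truncated: bool
    rise_words: int | None = None
    recovery_words: int | None = None

    @property
    def rise_rate(self) -> float | None:
        if self.rise_words is None:
            return None
        return self.peak_distance / self.rise_words

    @property
    def recovery_rate(self) -> float | None:
        if self.recovery_words is None:
            return None
        return self.peak_distance / self.recovery_words


@dataclass
class UEDProfile:
    """Per-speaker summary row of all metrics.

    Averages over displacements are ``None`` ("not available") when fewer
    than ``min_displacements`` non-truncated excursions exist.
    """

    speaker: str
    movie_id: str
    n_turns: int
    n_tokens: int
    n_vad_words: int
    densities: dict[str, float | None]  # percent per category
    mean_valence: float | None
    mean_arousal: float | None
    home_band_v: HomeBase1D | None
    home_band_a: HomeBase1D | None
    home_ellipse: HomeBaseEllipse | None
    variability_v: float | None
    variability_a: float | None
    variability_2d: float | None
    displacement_count: int
    n_usable_displacements: int
    mean_displacement_length: float | None
    mean_peak_distance: float | None
    mean_rise_rate: float | None
    mean_recovery_rate: float | None
    displacements: list[Displacement] = field(default_factory=list)

    def to_row(self) -> dict:
        """Flatten to a CSV-friendly record (one profile table row)."""
        row: dict = {
            "movie_id": self.movie_id,
            "speaker": self.speaker,
            "n_turns": self.n_turns,
            "n_tokens": self.n_tokens,
            "n_vad_words": self.n_vad_words,
        }
        for cat in sorted(CATEGORIES):
            row[f"density_{cat}"] = self.densities.get(cat)
        row["mean_valence"] = self.mean_valence
        row["mean_arousal"] = self.mean_arousal
        if self.home_ellipse is not None:
            row["home_cv"] = float(self.home_ellipse.center[0])
            row["home_ca"] = float(self.home_ellipse.center[1])
            row["home_semi_major"] = self.home_ellipse.semi_major
            row["home_semi_minor"] = self.home_ellipse.semi_minor
            row["home_theta"] = self.home_ellipse.theta
        else:
            row.update(
                home_cv=None, home_ca=None, home_semi_major=None, home_semi_minor=None, home_theta=None
            )
        row["variability_v"] = self.variability_v
        row["variability_a"] = self.variability_a
        row["variability_2d"] = self.variability_2d
        row["displacement_count"] = self.displacement_count
        row["n_usable_displacements"] = self.n_usable_displacements
        row["mean_displacement_length"] = self.mean_displacement_length
        row["mean_peak_distance"] = self.mean_peak_distance
        row["mean_rise_rate"] = self.mean_rise_rate
        row["mean_recovery_rate"] = self.mean_recovery_rate
        return row


def emotion_word_density(
    tokens: Sequence[str], lexicon: CategoricalLexicon, category: str
) -> float | None:
    """Percentage of tokens flagged with ``category`` (all tokens count).

    The denominator includes tokens absent from the lexicon; an empty
    token list has no defined density and returns ``None``.
    """
    if category not in CATEGORIES:
        raise ValueError(f"unknown category {category!r}")
    if not tokens:
        return None
    hits = sum(1 for t in tokens if lexicon.has_category(t, category))
    return 100.0 * hits / len(tokens)


def dimensional_density(scored: Sequence[ScoredWord]) -> tuple[float, float] | None:
    """Mean valence and arousal over lexicon-covered words (``None`` if empty)."""
    if not scored:
        return None
    v = float(np.mean([w.valence for w in scored]))
    a = float(np.mean([w.arousal for w in scored]))
    return v, a


def variability(series: Sequence[float]) -> float:
    """Population-denominator standard deviation of a score series."""
    x = np.asarray(series, dtype=float)
    if x.size < 1:
        raise ValueError("variability requires at least 1 value")
    return float(x.std())  # ddof=0


def variability_2d(points) -> float:
    """Mean of the valence SD and arousal SD of a trajectory or (n,2) array."""
    if len(points) and hasattr(points[0], "v"):
        va = trajectory_va(points)
    else:
        va = np.asarray(points, dtype=float)
    if va.ndim != 2 or va.shape[0] < 1:
        raise ValueError("variability_2d requires at least 1 (v, a) point")
    return float((va[:, 0].std() + va[:, 1].std()) / 2.0)


def detect_displacements(
    traj: Sequence[TrajectoryPoint],
    home: HomeBaseEllipse,
    distance_method: str = "radial",
) -> list[Displacement]:
    """Segment a trajectory into excursions outside the home base.

    Each maximal run of consecutive outside points bounded by inside
    points on both sides is one displacement; runs touching either end of
    the trajectory are returned with ``truncated=True``.  The peak is the
    outside point maximizing perimeter distance (earliest index wins
    ties); rise/recovery word counts run from the last inside point to the
    peak and from the peak to the first inside point after return.
    """
    if not traj:
        return []
    inside = np.array([contains(home, (p.v, p.a)) for p in traj], dtype=bool)
    dists = np.array(
        [0.0 if inside[i] else perimeter_distance(home, (traj[i].v, traj[i].a), distance_method) for i in range(len(traj))]
    )
    displacements: list[Displacement] = []
    n = len(traj)
    i = 0
    while i < n:
        if inside[i]:
            i += 1
            continue
        j = i
        while j < n and not inside[j]:
            j += 1
        # outside run is [i, j)
        run = dists[i:j]
        peak_offset = int(np.argmax(run))  # earliest max
        peak_index = i + peak_offset
        truncated = (i == 0) or (j == n)
        exit_index = i - 1 if i > 0 else None
        return_index = j if j < n else None
        disp = Displacement(
            exit_index=exit_index,
            first_out_index=i,
            peak_index=peak_index,
            return_index=return_index,
            length=j - i,
            peak_distance=float(run[peak_offset]),
            truncated=truncated,
        )
        if exit_index is not None:
            disp.rise_words = peak_index - exit_index
        if return_index is not None:
            disp.recovery_words = return_index - peak_index
        displacements.append(disp)
        i = j
    return displacements


def _mean_or_none(values: list[float], min_n: int) -> float | None:
    if len(values) < min_n:
        return None
    return float(np.mean(values))


def summarize_profile(
    narrative: CharacterNarrative,
    vad_lexicon: DimensionalLexicon,
    emotion_lexicon: CategoricalLexicon,
    window: int = 10,
    confidence: float = 0.68,
    min_displacements: int = 5,
    stat_basis: str = "trajectory",
    distance_method: str = "radial",
) -> UEDProfile:
    """Assemble the full metric profile for one speaker.

    ``stat_basis`` selects whether home bases and variability are computed
    on the rolling trajectory (default) or on raw word scores; densities
    and mean valence/arousal always use raw tokens/scores.  Displacement
    averages use non-truncated excursions only and are withheld when fewer
    than ``min_displacements`` exist.
    """
    if stat_basis not in ("trajectory", "raw"):
        raise ValueError("stat_basis must be 'trajectory' or 'raw'")
    scored = score_words(narrative, vad_lexicon)
    traj = rolling_trajectory(scored, window=window, movie_total_tokens=narrative.movie_total_tokens)

    densities = {
        cat: emotion_word_density(narrative.tokens, emotion_lexicon, cat)
        for cat in sorted(CATEGORIES)
    }
    dim = dimensional_density(scored)
    mean_v, mean_a = dim if dim is not None else (None, None)

    if stat_basis == "trajectory":
        basis = trajectory_va(traj) if traj else np.empty((0, 2))
    else:
        basis = np.array([[w.valence, w.arousal] for w in scored], float).reshape(-1, 2)

    band_v = band_a = ellipse = None
    var_v = var_a = var_2d = None
    if basis.shape[0] >= 1:
        var_v = variability(basis[:, 0])
        var_a = variability(basis[:, 1])
        var_2d = (var_v + var_a) / 2.0
    if basis.shape[0] >= 2:
        band_v = home_base_1d(basis[:, 0], confidence)
        band_a = home_base_1d(basis[:, 1], confidence)
    if basis.shape[0] >= 3:
        try:
            ellipse = home_base_2d(basis, confidence)
        except ValueError:
            ellipse = None  # degenerate cloud: no 2-D home base

    displacements: list[Displacement] = []
    if ellipse is not None and traj:
        displacements = detect_displacements(traj, ellipse, distance_method)
    usable = [d for d in displacements if not d.truncated]
    count = len(usable)

    return UEDProfile(
        speaker=narrative.speaker,
        movie_id=narrative.movie_id,
        n_turns=narrative.n_turns,
        n_tokens=len(narrative.tokens),
        n_vad_words=len(scored),
        densities=densities,
        mean_valence=mean_v,
        mean_arousal=mean_a,
        home_band_v=band_v,
        home_band_a=band_a,
        home_ellipse=ellipse,
        variability_v=var_v,
        variability_a=var_a,
        variability_2d=var_2d,
        displacement_count=count,
        n_usable_displacements=count,
        mean_displacement_length=_mean_or_none([float(d.length) for d in usable], min_displacements),
        mean_peak_distance=_mean_or_none([d.peak_distance for d in usable], min_displacements),
        mean_rise_rate=_mean_or_none([d.rise_rate for d in usable if d.rise_rate is not None], min_displacements),
        mean_recovery_rate=_mean_or_none(
            [d.recovery_rate for d in usable if d.recovery_rate is not None], min_displacements
        ),
        displacements=displacements,
    )
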