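"""Cross-speaker and narrative-time analyses.

*Discordance* is the Euclidean distance in valence-arousal space between
two speakers' trajectory positions at the same normalized narrative time.
Trajectories are aligned on a grid of ``n_bins`` time bins (centers at
``(k + 0.5) / n_bins``, i.e. movie percentage points at the default 100):
each speaker's points falling in a bin are averaged, interior empty bins
are filled by linear interpolation between occupied neighbours, and bins
before a speaker's first or after their last occupied bin stay missing —
no emotional state is invented where a character is absent.

*Density arcs* track a category's emotion word density in a rolling
window (default 30 words, all tokens in the denominator) over narrative
time; a penalized cubic smoothing spline (smoothing chosen by generalized
cross-validation, overridable) extracts the trend, whose extremum
location answers questions such as "where does negative density peak?".
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.interpolate import make_smoothing_spline

from .lexicons import CategoricalLexicon
from .trajectory import TrajectoryPoint, normalized_time
from .transcripts import CharacterNarrative

__all__ = [
    "DiscordanceSeries",
    "DensityArc",
    "TrendCurve",
    "Extremum",
    "eligible_pairs",
    "discordance_series",
    "density_arc",
    "fit_trend",
    "locate_extremum",
    "correlate_series",
    "permutation_slope_test",
]


@dataclass
class DiscordanceSeries:
    """Per-bin emotional distance between an unordered speaker pair.

    ``distance`` is NaN where either speaker has no (interpolated)
    position; ``support_a``/``support_b`` count raw trajectory points per
    bin before interpolation.
    """

    movie_id: str
    speakers: tuple[str, str]  # sorted
    t: np.ndarray  # bin centers
    distance: np.ndarray  # NaN = missing
    support_a: np.ndarray
    support_b: np.ndarray

    @property
    def mean_distance(self) -> float:
        return float(np.nanmean(self.distance))


@dataclass
class DensityArc:
    """Rolling emotion-word density of one speaker over narrative time."""

    speaker: str
    category: str
    t: np.ndarray
    density: np.ndarray  # percent


@dataclass
class TrendCurve:
    """Penalized-spline smooth of y over normalized time.

    Evaluation outside the fitted x-range is clamped to the boundary
    value (constant extension, no extrapolation).
    """

    spline: object
    x_min: float
    x_max: float
    lam: float | None
    residual_scale: float

    def __call__(self, grid) -> np.ndarray:
        g = np.clip(np.asarray(grid, dtype=float), self.x_min, self.x_max)
        return np.asarray(self.spline(g), dtype=float)


@dataclass
class Extremum:
    """Location of a trend curve's max/min on [0, 1]."""

    t: float
    value: float
    kind: str
    boundary: bool  # extremum sits at a grid or data-range boundary
    distinct: bool  # False when the curve is flat within tolerance


def eligible_pairs(
    narratives: Sequence[CharacterNarrative], edge_fraction: float = 0.10
) -> list[tuple[str, str]]:
    """Unordered pairs of speakers present in both narrative edges.

    A speaker qualifies with at least one token in the first
    ``edge_fraction`` and one in the last ``edge_fraction`` of the
    movie's normalized time, so paired characters span comparable
    narrative lengths.
    """
    qualifying = []
    for nar in narratives:
        if nar.empty:
            continue
        total = nar.movie_total_tokens
        ts = [normalized_time(p, total) for p in (nar.positions[0], nar.positions[-1])]
        if ts[0] < edge_fraction and ts[-1] > 1.0 - edge_fraction:
            qualifying.append(nar.speaker)
    qualifying.sort()
    return list(itertools.combinations(qualifying, 2))


def _binned_positions(
    traj: Sequence[TrajectoryPoint], n_bins: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-bin mean (v, a) with interior gaps linearly interpolated.

    Returns ``(va, support)``: ``va`` is (n_bins, 2) with NaN outside the
    speaker's occupied range, ``support`` the raw point count per bin.
    """
    va = np.full((n_bins, 2), np.nan)
    support = np.zeros(n_bins, dtype=int)
    sums = np.zeros((n_bins, 2))
    for p in traj:
        if p.t is None:
            raise ValueError("trajectory points need movie-global normalized time")
        b = min(int(p.t * n_bins), n_bins - 1)
        sums[b, 0] += p.v
        sums[b, 1] += p.a
        support[b] += 1
    occupied = support > 0
    if not occupied.any():
        raise ValueError("speaker has no occupied time bins")
    va[occupied] = sums[occupied] / support[occupied, None]
    # linear interpolation across interior gaps only
    idx = np.flatnonzero(occupied)
    lo, hi = idx[0], idx[-1]
    centers = (np.arange(n_bins) + 0.5) / n_bins
    for dim in range(2):
        va[lo : hi + 1, dim] = np.interp(
            centers[lo : hi + 1], centers[occupied], va[occupied, dim]
        )
    return va, support


def discordance_series(
    traj_a: Sequence[TrajectoryPoint],
    traj_b: Sequence[TrajectoryPoint],
    n_bins: int = 100,
    movie_id: str = "",
    speakers: tuple[str, str] = ("A", "B"),
) -> DiscordanceSeries:
    """Per-bin Euclidean v-a distance between two speakers' trajectories.

    Symmetric in the pair; bins where either speaker is absent (outside
    their occupied range) are NaN.
    """
    va_a, sup_a = _binned_positions(traj_a, n_bins)
    va_b, sup_b = _binned_positions(traj_b, n_bins)
    dist = np.linalg.norm(va_a - va_b, axis=1)
    centers = (np.arange(n_bins) + 0.5) / n_bins
    spk = tuple(sorted(speakers))
    if spk != tuple(speakers):
        sup_a, sup_b = sup_b, sup_a
    return DiscordanceSeries(
        movie_id=movie_id,
        speakers=spk,  # type: ignore[arg-type]
        t=centers,
        distance=dist,
        support_a=sup_a,
        support_b=sup_b,
    )


def density_arc(
    narrative: CharacterNarrative,
    lexicon: CategoricalLexicon,
    category: str,
    window: int = 30,
) -> DensityArc:
    """Rolling emotion-word density (%) over trailing full windows.

    All tokens count in the denominator (consistent with emotion word
    density); each point is timestamped at the window's last token's
    movie-global normalized time.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    n = len(narrative.tokens)
    if n < window:
        warnings.warn(
            f"narrative of {narrative.speaker!r} shorter than density window ({n} < {window})"
        )
        return DensityArc(narrative.speaker, category, np.empty(0), np.empty(0))
    flags = np.array(
        [1.0 if lexicon.has_category(t, category) else 0.0 for t in narrative.tokens]
    )
    csum = np.concatenate([[0.0], np.cumsum(flags)])
    counts = csum[window:] - csum[:-window]
    dens = 100.0 * counts / window
    ts = np.array(
        [
            normalized_time(narrative.positions[k + window - 1], narrative.movie_total_tokens)
            for k in range(n - window + 1)
        ]
    )
    return DensityArc(narrative.speaker, category, ts, dens)


def fit_trend(x, y, lam: float | None = None) -> TrendCurve:
    """Penalized cubic smoothing spline of y on normalized time x.

    Smoothing is chosen by generalized cross-validation unless ``lam`` is
    given.  Requires >= 20 points spanning at least half of [0, 1];
    duplicate x values are weight-averaged before fitting.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 20:
        raise ValueError("fit_trend requires at least 20 points")
    if np.ptp(x) < 1e-12:
        raise ValueError("degenerate x: all values equal")
    if np.ptp(x) < 0.5:
        raise ValueError("x must span at least half of [0, 1]")
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    # collapse duplicates to weighted means (spline needs strictly increasing x)
    xu, start = np.unique(xs, return_index=True)
    counts = np.diff(np.append(start, xs.size)).astype(float)
    ycum = np.concatenate([[0.0], np.cumsum(ys)])
    bounds = np.append(start, xs.size)
    yu = (ycum[bounds[1:]] - ycum[bounds[:-1]]) / counts
    if xu.size < 4:
        raise ValueError("fit_trend requires at least 4 distinct x values")
    spline = make_smoothing_spline(xu, yu, w=counts, lam=lam)
    resid = yu - np.asarray(spline(xu), dtype=float)
    scale = float(np.sqrt(np.average(resid**2, weights=counts)))
    return TrendCurve(
        spline=spline, x_min=float(xu[0]), x_max=float(xu[-1]), lam=lam, residual_scale=scale
    )


def locate_extremum(
    curve: TrendCurve, kind: str = "max", grid_size: int = 1001, flat_tol: float = 1e-9
) -> Extremum:
    """Arg-extremum of a trend curve over an even grid on [0, 1].

    Boundary extrema (at the grid ends or the fitted data range's ends)
    carry ``boundary=True``; a curve whose range is below ``flat_tol`` is
    flagged ``distinct=False`` (no distinct extremum).
    """
    if kind not in ("max", "min"):
        raise ValueError("kind must be 'max' or 'min'")
    grid = np.linspace(0.0, 1.0, grid_size)
    values = curve(grid)
    flat = float(np.ptp(values)) < flat_tol
    k = int(np.argmax(values)) if kind == "max" else int(np.argmin(values))
    t_star = float(grid[k])
    eps = 1.0 / (grid_size - 1)
    boundary = (
        k == 0
        or k == grid_size - 1
        or t_star <= curve.x_min + eps
        or t_star >= curve.x_max - eps
    )
    return Extremum(t=t_star, value=float(values[k]), kind=kind, boundary=boundary, distinct=not flat)


def correlate_series(x, y) -> float | None:
    """Pearson r over aligned non-missing bins (``None`` if undefined).

    Requires >= 3 aligned points and non-constant inputs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("series must share a common grid")
    mask = ~(np.isnan(x) | np.isnan(y))
    xs, ys = x[mask], y[mask]
    if xs.size < 3:
        return None
    if np.ptp(xs) < 1e-15 or np.ptp(ys) < 1e-15:
        return None
    return float(stats.pearsonr(xs, ys)[0])


def permutation_slope_test(
    x, y, n_permutations: int = 999, seed: int = 0
) -> tuple[float, float]:
    """Permutation check of a linear time trend (descriptive alternative
    to model-based significance testing).

    Shuffles y over the bins and recomputes the least-squares slope;
    returns ``(observed_slope, p_value)`` where p is the two-sided
    permutation fraction with the +1 correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = ~(np.isnan(x) | np.isnan(y))
    xs, ys = x[mask], y[mask]
    if xs.size < 3:
        raise ValueError("need at least 3 points")
    slope = float(np.polyfit(xs, ys, 1)[0])
    rng = np.random.default_rng(seed)
    extreme = 0
    for _ in range(n_permutations):
        perm = rng.permutation(ys)
        if abs(float(np.polyfit(xs, perm, 1)[0])) >= abs(slope):
            extreme += 1
    return slope, (extreme + 1) / (n_permutations + 1)
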