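"""Home-base estimation: where a speaker's emotional location usually is.

The 1-D home base of a score series is the confidence band

    mean +/- t_crit * sqrt(sigma^2 / N)

with ``sigma^2`` the population-denominator variance and ``t_crit`` the
two-sided Student-t critical value at the requested coverage (e.g. 68%,
one standard deviation) with N-1 degrees of freedom.

The 2-D home base in valence-arousal space is the covariance confidence
ellipse: centered on the component means, axes along the eigenvectors of
the (population) covariance matrix, semi-axes ``sqrt(psi * lambda_i)``
where ``psi`` is the chi-square(2 df) quantile at the coverage level
(~2.2789 at 68%).  A point x is inside when, with c the center and e1, e2
the eigenvectors,

    ((x-c).e1)^2 / (psi lambda_1) + ((x-c).e2)^2 / (psi lambda_2) <= 1

(the boundary counts as inside).

Distance from a point to the home-base perimeter defaults to the *radial*
convention: the Euclidean length from the point to the boundary along the
ray from the center through the point.  It is a deterministic closed form,
order-preserving along a single excursion, and coincides with
``|p - c| - r`` in the circular limit.  The exact orthogonal
(nearest-point) distance is available via ``method="nearest"``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "HomeBase1D",
    "HomeBaseEllipse",
    "DegenerateGeometryError",
    "home_base_1d",
    "home_base_2d",
    "contains",
    "perimeter_distance",
]

#: eigenvalues below this are treated as degenerate geometry
DEGENERACY_TOL = 1e-12

# boundary membership tolerance on the quadratic form
_BOUNDARY_TOL = 1e-9


class DegenerateGeometryError(ValueError):
    """Covariance is rank-deficient: the ellipse would have a zero axis."""


@dataclass
class HomeBase1D:
    """Confidence band for a single emotion dimension."""

    mean: float
    half_width: float
    confidence: float
    n: int
    variance: float
    t_crit: float

    @property
    def lower(self) -> float:
        return self.mean - self.half_width

    @property
    def upper(self) -> float:
        return self.mean + self.half_width

    def contains(self, value: float) -> bool:
        return self.lower <= value <= self.upper


@dataclass
class HomeBaseEllipse:
    """Covariance confidence ellipse in valence-arousal space.

    ``eigenvectors`` holds orthonormal columns: column 0 is the major-axis
    direction (eigenvalue ``lambda1``), column 1 the minor axis.
    """

    center: np.ndarray  # shape (2,): (v_mean, a_mean)
    lambda1: float  # larger eigenvalue
    lambda2: float
    eigenvectors: np.ndarray  # shape (2, 2), columns e1, e2
    psi: float  # chi-square(2) critical value
    confidence: float
    n: int

    @property
    def semi_major(self) -> float:
        return float(np.sqrt(self.psi * self.lambda1))

    @property
    def semi_minor(self) -> float:
        return float(np.sqrt(self.psi * self.lambda2))

    @property
    def theta(self) -> float:
        """Orientation of the major axis, radians in (-pi/2, pi/2]."""
        e1 = self.eigenvectors[:, 0]
        ang = float(np.arctan2(e1[1], e1[0]))
        if ang <= -np.pi / 2:
            ang += np.pi
        elif ang > np.pi / 2:
            ang -= np.pi
        return ang

    @property
    def area(self) -> float:
        return float(np.pi * self.semi_major * self.semi_minor)

    def radius_along(self, direction: np.ndarray) -> float:
        """Ellipse radius (center to boundary) along a direction vector."""
        u = np.asarray(direction, dtype=float)
        u = u / np.linalg.norm(u)
        q = self._unit_quadratic_form(u)
        return float(1.0 / np.sqrt(q))

    def _unit_quadratic_form(self, x: np.ndarray) -> float:
        c1 = float(x @ self.eigenvectors[:, 0])
        c2 = float(x @ self.eigenvectors[:, 1])
        return c1 * c1 / (self.psi * self.lambda1) + c2 * c2 / (self.psi * self.lambda2)

    def quadratic_form(self, point) -> float:
        """Value of the ellipse quadratic form at ``point`` (1 on the boundary)."""
        x = np.asarray(point, dtype=float) - self.center
        return self._unit_quadratic_form(x)


def home_base_1d(series: Sequence[float], confidence: float = 0.68) -> HomeBase1D:
    """Confidence band around the mean of a score series.

    Uses the population (divide-by-N) variance and the two-sided t
    critical value ``t.ppf(1 - (1 - confidence) / 2, N - 1)``.  A
    zero-variance series yields a degenerate band of width 0.
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("home_base_1d requires at least 2 values")
    if not 0.0 < confidence < 1.0:
        raise ValueError("confidence must be in (0, 1)")
    mean = float(x.mean())
    var = float(x.var())  # ddof=0
    t_crit = float(stats.t.ppf(1.0 - (1.0 - confidence) / 2.0, n - 1))
    half_width = t_crit * float(np.sqrt(var / n))
    return HomeBase1D(
        mean=mean, half_width=half_width, confidence=confidence, n=n, variance=var, t_crit=t_crit
    )


def home_base_2d(points, confidence: float = 0.68) -> HomeBaseEllipse:
    """Covariance confidence ellipse of a set of (v, a) locations.

    ``points`` is an ``(n, 2)`` array or a sequence of trajectory points
    with ``v``/``a`` attributes; n >= 3 and a full-rank covariance are
    required.  Collinear or constant clouds raise
    :class:`DegenerateGeometryError` naming the deficient axis.
    """
    va = _as_va(points)
    n = va.shape[0]
    if n < 3:
        raise ValueError("home_base_2d requires at least 3 points")
    if not 0.0 < confidence < 1.0:
        raise ValueError("confidence must be in (0, 1)")
    center = va.mean(axis=0)
    cov = np.cov(va.T, ddof=0)
    eigvals, eigvecs = np.linalg.eigh(cov)  # ascending
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    lam1, lam2 = float(eigvals[0]), float(eigvals[1])
    if lam1 < DEGENERACY_TOL:
        raise DegenerateGeometryError(
            "all points coincide: both ellipse axes are degenerate"
        )
    if lam2 < DEGENERACY_TOL:
        raise DegenerateGeometryError(
            "points are collinear: minor axis is degenerate"
        )
    psi = float(stats.chi2.ppf(confidence, df=2))
    return HomeBaseEllipse(
        center=center,
        lambda1=lam1,
        lambda2=lam2,
        eigenvectors=eigvecs,
        psi=psi,
        confidence=confidence,
        n=n,
    )


def _as_va(points) -> np.ndarray:
    arr = np.asarray(points, dtype=float) if not _has_va(points) else None
    if arr is None:
        arr = np.array([[p.v, p.a] for p in points], dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("expected an (n, 2) array of (v, a) points")
    return arr


def _has_va(points) -> bool:
    try:
        first = points[0]
    except (IndexError, KeyError, TypeError):
        return False
    return hasattr(first, "v") and hasattr(first, "a")


def contains(ellipse: HomeBaseEllipse, point) -> bool:
    """True iff ``point`` is inside the ellipse (boundary counts as inside)."""
    return ellipse.quadratic_form(point) <= 1.0 + _BOUNDARY_TOL


def perimeter_distance(
    ellipse: HomeBaseEllipse, point, method: str = "radial"
) -> float:
    """Euclidean distance from a point to the home-base perimeter (0 inside).

    ``method="radial"`` (default) measures along the center ray; with
    ``q`` the quadratic-form value at the point this is
    ``|p - c| * (1 - q**-0.5)``.  ``method="nearest"`` solves for the true
    nearest boundary point (tolerance 1e-9).
    """
    q = ellipse.quadratic_form(point)
    if q <= 1.0 + _BOUNDARY_TOL:
        return 0.0
    x = np.asarray(point, dtype=float) - ellipse.center
    if method == "radial":
        return float(np.linalg.norm(x) * (1.0 - 1.0 / np.sqrt(q)))
    if method == "nearest":
        return _nearest_boundary_distance(ellipse, x)
    raise ValueError(f"unknown method {method!r}; use 'radial' or 'nearest'")


def _nearest_boundary_distance(ellipse: HomeBaseEllipse, x: np.ndarray) -> float:
    """Exact point-to-ellipse distance for an exterior point.

    Works in the principal frame with semi-axes A >= B and the point
    folded to the first quadrant; solves
    f(t) = (A px / (t + A^2))^2 + (B py / (t + B^2))^2 - 1 = 0 on
    t in (-B^2, inf), where f is strictly decreasing.
    """
    A, B = ellipse.semi_major, ellipse.semi_minor
    px = abs(float(x @ ellipse.eigenvectors[:, 0]))
    py = abs(float(x @ ellipse.eigenvectors[:, 1]))
    if px == 0.0 and py == 0.0:
        return 0.0  # center (inside); not reachable from perimeter_distance

    def f(t: float) -> float:
        return (A * px / (t + A * A)) ** 2 + (B * py / (t + B * B)) ** 2 - 1.0

    # exterior point => root lies in (max(-B^2, ...), upper); bracket upward
    lo = -B * B + 1e-15 if py > 0 else -B * B + 1e-15
    if py == 0.0:
        # nearest point may be the axis vertex when px <= A - B^2/A is false
        if px >= A:
            return px - A
        # px < A with py=0 can only happen inside; fall through defensively
        return max(px - A, 0.0)
    hi = max(A * px + B * py, 1.0)
    while f(hi) > 0:
        hi *= 2.0
    t_star = optimize.brentq(f, lo, hi, xtol=1e-15, rtol=8.9e-16, maxiter=200)
    bx = A * A * px / (t_star + A * A)
    by = B * B * py / (t_star + B * B)
    return float(np.hypot(px - bx, py - by))
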