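"""Bivariate standard-ellipse statistics and ancillary tests.

The standard ellipse of a bivariate sample is the 1σ contour implied by
the sample covariance matrix: centred on the mean, semi-axes equal to
the square roots of the covariance eigenvalues, major axis inclined at
θ to the positive x axis.  For bivariate-normal data it contains
≈ 39.35 % (1 − e^{−1/2}) of the points.  The sample-size-corrected area
SEAc = π·a·b·(n−1)/(n−2) removes the small-sample bias of the plain
ellipse area.

Also provided: points of tangency of the axis-parallel tangent lines
(which lie on the two regression lines), ordinary least squares, and the
Mann-Whitney rank-sum test (both via scipy).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "EllipseSummary",
    "standard_ellipse",
    "ellipse_from_moments",
    "containment_fraction",
    "mahalanobis_sq",
    "tangency_points",
    "ols_line",
    "mann_whitney",
]

_DEGENERATE_RTOL = 1e-12


@dataclass
class EllipseSummary:
    """Standard-ellipse summary of a bivariate sample (one table row).

    ``a``/``b`` are the semi-major/minor axes (eigenvalue square roots of
    the sample covariance), ``theta`` the major-axis inclination in
    [0, π), ``slope`` = tan(theta), and ``area_c`` the sample-size
    corrected ellipse area π·a·b·(n−1)/(n−2).
    """

    n: int
    mean_x: float
    mean_y: float
    sd_x: float
    sd_y: float
    r: float
    a: float
    b: float
    theta: float
    slope: float
    area_c: float
    degenerate: bool = False

    @property
    def cov(self) -> float:
        return self.r * self.sd_x * self.sd_y

    def covariance_matrix(self) -> np.ndarray:
        c = self.cov
        return np.array([[self.sd_x**2, c], [c, self.sd_y**2]])


def ellipse_from_moments(
    mean_x: float, mean_y: float, sd_x: float, sd_y: float, r: float, n: int
) -> EllipseSummary:
    """Build an :class:`EllipseSummary` from bivariate summary statistics.

    This is the route from a printed table row (mean ± σ per axis,
    Pearson r, n) back to semi-axes, orientation and corrected area.
    """
    if n < 3:
        raise ValueError("insufficient points: need n >= 3")
    if not -1.0 <= r <= 1.0:
        raise ValueError("correlation must lie in [-1, 1]")
    sx2, sy2 = sd_x**2, sd_y**2
    cov = r * sd_x * sd_y
    # closed-form eigenvalues of the 2x2 covariance matrix
    mean_eig = (sx2 + sy2) / 2.0
    half_gap = math.hypot((sx2 - sy2) / 2.0, cov)
    lam1 = mean_eig + half_gap
    lam2 = max(mean_eig - half_gap, 0.0)
    a = math.sqrt(lam1)
    degenerate = lam1 <= 0 or lam2 <= lam1 * _DEGENERATE_RTOL
    b = 0.0 if degenerate else math.sqrt(lam2)

    if cov == 0.0 and sx2 == sy2:
        theta = 0.0  # circular cloud: orientation undefined, tie-break to 0
    else:
        theta = 0.5 * math.atan2(2.0 * cov, sx2 - sy2)
        if theta < 0:
            theta += math.pi
        if theta >= math.pi:  # guard against round-up of a tiny negative angle
            theta = 0.0
    if cov != 0.0:
        # equivalent to tan(theta) but stable near theta = pi/2
        slope = (lam1 - sx2) / cov
    else:
        slope = 0.0 if sx2 >= sy2 else math.inf

    area_c = math.pi * a * b * (n - 1) / (n - 2)
    return EllipseSummary(
        n=n, mean_x=mean_x, mean_y=mean_y, sd_x=sd_x, sd_y=sd_y, r=r,
        a=a, b=b, theta=theta, slope=slope, area_c=area_c, degenerate=degenerate,
    )


def standard_ellipse(x, y) -> EllipseSummary:
    """Standard-ellipse summary of paired samples.

    Sample statistics use the n−1 denominator.  Exactly collinear input
    yields a degenerate summary (b = 0, zero area) rather than an error.

    Raises
    ------
    ValueError
        If fewer than 3 points, mismatched lengths, or zero variance in
        both coordinates.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    n = x.size
    if n < 3:
        raise ValueError("insufficient points: need n >= 3")
    sd_x = float(np.std(x, ddof=1))
    sd_y = float(np.std(y, ddof=1))
    if sd_x == 0.0 and sd_y == 0.0:
        raise ValueError("zero variance in both coordinates")
    cov = float(np.cov(x, y, ddof=1)[0, 1])
    r = 0.0 if sd_x == 0.0 or sd_y == 0.0 else cov / (sd_x * sd_y)
    r = min(1.0, max(-1.0, r))
    return ellipse_from_moments(float(np.mean(x)), float(np.mean(y)), sd_x, sd_y, r, n)


def mahalanobis_sq(x, y, ellipse: EllipseSummary) -> np.ndarray:
    """Squared Mahalanobis distance of points from the ellipse centre."""
    if ellipse.degenerate:
        raise ValueError("degenerate ellipse")
    dx = np.asarray(x, dtype=float) - ellipse.mean_x
    dy = np.asarray(y, dtype=float) - ellipse.mean_y
    sx2, sy2, c = ellipse.sd_x**2, ellipse.sd_y**2, ellipse.cov
    det = sx2 * sy2 - c * c
    return (sy2 * dx * dx - 2.0 * c * dx * dy + sx2 * dy * dy) / det


def containment_fraction(x, y, ellipse: EllipseSummary) -> float:
    """Fraction of points inside the ellipse (Mahalanobis² ≤ 1).

    For a large bivariate-normal cloud and its own standard ellipse this
    converges to 1 − e^{−1/2} ≈ 0.3935 — the "∼40 % of the data" property.
    """
    d2 = mahalanobis_sq(x, y, ellipse)
    return float(np.mean(d2 <= 1.0))


def tangency_points(ellipse: EllipseSummary) -> np.ndarray:
    """The four tangency points of the axis-parallel tangent lines.

    Vertical tangents touch at (x̄ ± σₓ, ȳ ± r·σ_y); horizontal tangents
    at (x̄ ± r·σₓ, ȳ ± σ_y).  Each lies on the ellipse boundary and on
    the corresponding regression line.  Returned as a (4, 2) array.
    """
    if ellipse.degenerate:
        raise ValueError("degenerate ellipse")
    mx, my = ellipse.mean_x, ellipse.mean_y
    sx, sy, r = ellipse.sd_x, ellipse.sd_y, ellipse.r
    return np.array(
        [
            [mx + sx, my + r * sy],
            [mx - sx, my - r * sy],
            [mx + r * sx, my + sy],
            [mx - r * sx, my - sy],
        ]
    )


def ols_line(x, y) -> tuple[float, float, float]:
    """Ordinary least squares of y on x: (slope, intercept, R²)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("insufficient points: need n >= 3")
    if np.var(x) == 0:
        raise ValueError("zero variance in x")
    fit = stats.linregress(x, y)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue**2)


def mann_whitney(x, y) -> tuple[float, float]:
    """Mann-Whitney U rank-sum test, two-sided: (U of x, p-value).

    Uses exact enumeration when n₁·n₂ ≤ 400 and the pooled sample has no
    ties; otherwise the normal approximation with tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (x.size * y.size <= 400 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)
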