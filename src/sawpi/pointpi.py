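"""Empirical pi from 2-D point patterns by quarter-circle quadrant counting.

This is the computational content of counting DNA nanostructures (hairpin or
ring centroids) in square microscope fields: inscribe a quarter circle whose
radius equals the field's side at one corner, count the points inside, and
estimate ``pi_exp = 4 * n_inside / n_total``.  Four quadrants fit one image,
giving four estimates per field.  A synthetic generator produces uniform
point fields standing in for imaged centroid patterns; real fields' point
densities track DNA concentration, which enters here only through the point
count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .dartpi import pi_from_counts

__all__ = [
    "CORNERS",
    "PointPattern",
    "QuadrantSpec",
    "PointPiEstimate",
    "GeneratorSpec",
    "estimate_pi_points",
    "four_quadrant_estimates",
    "running_mean",
    "sorted_deviation",
    "generate_uniform_pattern",
]

CORNERS = ("bottom-left", "bottom-right", "top-left", "top-right")


@dataclass(frozen=True)
class PointPattern:
    """Point coordinates in a square field ``[0, width] x [0, height]``."""

    width: float
    height: float
    points: np.ndarray  # shape (n, 2)

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float).reshape(-1, 2)
        object.__setattr__(self, "points", pts)
        if self.width <= 0 or self.height <= 0:
            raise ValueError("field dimensions must be positive")
        if not math.isclose(self.width, self.height):
            raise ValueError("the field must be square (width == height)")
        if pts.size and (
            pts.min() < 0 or pts[:, 0].max() > self.width or pts[:, 1].max() > self.height
        ):
            raise ValueError("all points must lie inside the field")

    @property
    def n_points(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class QuadrantSpec:
    """A quarter circle inscribed in the square field at one corner."""

    corner: str
    radius: float

    def __post_init__(self) -> None:
        if self.corner not in CORNERS:
            raise ValueError(f"corner must be one of {CORNERS}, got {self.corner!r}")
        if self.radius <= 0:
            raise ValueError("radius must be positive")

    def origin(self, width: float, height: float) -> tuple[float, float]:
        x = 0.0 if "left" in self.corner else width
        y = 0.0 if "bottom" in self.corner else height
        return (x, y)


@dataclass(frozen=True)
class PointPiEstimate:
    """Counting estimate of pi from one quadrant of one point pattern."""

    n_total: int
    n_inside: int
    pi_exp: float = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        object.__setattr__(self, "pi_exp", pi_from_counts(self.n_inside, self.n_total))


@dataclass(frozen=True)
class GeneratorSpec:
    """Synthetic uniform point field: square width plus count or areal density."""

    width: float
    rng_seed: int
    n_points: int | None = None
    density: float | None = None  # points per unit area

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("width must be positive")
        if (self.n_points is None) == (self.density is None):
            raise ValueError("give exactly one of n_points or density")
        if self.n_points is None:
            object.__setattr__(self, "n_points", round(self.density * self.width**2))
        if self.n_points < 0:
            raise ValueError("n_points must be non-negative")


def estimate_pi_points(pattern: PointPattern, quadrant: QuadrantSpec) -> PointPiEstimate:
    """Count points within ``radius`` of the quadrant corner (boundary inside).

    Raises ``ValueError`` on an empty pattern: the estimator is undefined with
    no points (display layers may render such fields as 0.00, but that is a
    presentation convention, not arithmetic).
    """
    if pattern.n_points == 0:
        raise ValueError("pi_exp is undefined for an empty point pattern")
    ox, oy = quadrant.origin(pattern.width, pattern.height)
    d2 = (pattern.points[:, 0] - ox) ** 2 + (pattern.points[:, 1] - oy) ** 2
    n_inside = int(np.count_nonzero(d2 <= quadrant.radius**2))
    return PointPiEstimate(n_total=pattern.n_points, n_inside=n_inside)


def four_quadrant_estimates(pattern: PointPattern) -> dict[str, PointPiEstimate]:
    """One estimate per corner, radius equal to the field width."""
    return {
        corner: estimate_pi_points(pattern, QuadrantSpec(corner, pattern.width))
        for corner in CORNERS
    }


def running_mean(series) -> np.ndarray:
    """Cumulative means: element ``k`` averages the first ``k+1`` values."""
    arr = np.asarray(list(series), dtype=float)
    if arr.size == 0:
        raise ValueError("series must be non-empty")
    return np.cumsum(arr) / np.arange(1, arr.size + 1)


def sorted_deviation(series, pi_reference: float = math.pi) -> np.ndarray:
    """``|pi_exp - pi_reference|`` for each estimate, sorted descending."""
    arr = np.asarray(list(series), dtype=float)
    if arr.size == 0:
        raise ValueError("series must be non-empty")
    return np.sort(np.abs(arr - pi_reference))[::-1]


def generate_uniform_pattern(spec: GeneratorSpec) -> PointPattern:
    """``n_points`` i.i.d. uniform points in the square field; seed-reproducible."""
    rng = np.random.default_rng(np.random.SeedSequence(spec.rng_seed))
    pts = rng.random((spec.n_points, 2)) * spec.width
    return PointPattern(width=spec.width, height=spec.width, points=pts)
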