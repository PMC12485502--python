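"""The Reliability Volume (RV) metric.

RV summarises ``M`` training repetitions of a 3D task against an expert
*standard path* as an ordered pair ``(R, V)``:

* ``V = pi * d**2 * h`` is the volume of a cylindrical tube of radius ``d``
  coaxial with the standard path (``h`` is the standard path's arc length,
  or a fixed workspace height);
* ``R`` is the empirical probability that a repetition stays entirely
  inside that tube — the fraction of repetitions whose every pointwise
  deviation from the standard path is at most ``d``.

Sweeping ``d`` over the observed deviations yields the RV curve: the full
trade-off between tolerance volume and success probability.  The metric is
deliberately worst-case per repetition — a single excursion beyond the
tube radius makes that repetition a failure at that radius — so no
smoothing or outlier rejection is applied to the deviations.

A conventional *working volume* (sphere whose radius is the mean distance
of a path's points from a central point) is provided as the comparison
baseline.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .errors import AlignmentError, DomainError, EmptyInputError
from .paths import Path3D, RepetitionSet, arc_length

__all__ = [
    "DeviationMatrix",
    "ThresholdLadder",
    "RVPoint",
    "RVCurve",
    "pointwise_deviations",
    "threshold_ladder",
    "tube_volume",
    "reliability_at_threshold",
    "compute_rv_curve",
    "volume_at_reliability",
    "conventional_working_volume",
]

logger = logging.getLogger(__name__)

HMode = Literal["arclength", "fixed"]
LadderOrigin = Literal["full", "maxima"]


@dataclass(frozen=True)
class DeviationMatrix:
    """M x N grid of pointwise Euclidean deviations (cm).

    ``values[m, n]`` is the distance between point ``n`` of repetition ``m``
    and point ``n`` of the standard path.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.size == 0:
            raise EmptyInputError("deviation matrix must be a non-empty 2D array")
        if not np.all(np.isfinite(v)) or np.any(v < 0):
            raise DomainError("deviations must be finite and non-negative")
        object.__setattr__(self, "values", v)

    @property
    def M(self) -> int:
        return self.values.shape[0]

    @property
    def N(self) -> int:
        return self.values.shape[1]

    @property
    def per_path_max(self) -> np.ndarray:
        """Row maxima: the worst-case deviation of each repetition."""
        return self.values.max(axis=1)


@dataclass(frozen=True)
class ThresholdLadder:
    """Candidate tolerance radii, sorted descending, duplicates collapsed."""

    thresholds: np.ndarray
    origin: LadderOrigin = "maxima"

    def __post_init__(self) -> None:
        t = np.asarray(self.thresholds, dtype=float)
        if t.size == 0:
            raise EmptyInputError("threshold ladder is empty")
        if np.any(t < 0):
            raise DomainError("thresholds must be non-negative")
        if np.any(np.diff(t) >= 0):
            raise DomainError("thresholds must be strictly descending")
        object.__setattr__(self, "thresholds", t)

    def __len__(self) -> int:
        return self.thresholds.size


@dataclass(frozen=True)
class RVPoint:
    """One rung of the RV curve: (d, V, R, n) with V = pi d^2 h, R = n/M."""

    d: float
    volume: float
    reliability: float
    n_success: int


@dataclass(frozen=True)
class RVCurve:
    """The RV curve: RVPoints ordered by descending radius.

    The first point sits at the global maximum deviation, where every
    repetition conforms (R = 1); reliability is non-increasing as the
    radius shrinks along the list.
    """

    points: tuple[RVPoint, ...]
    h: float
    M: int
    h_mode: HMode = "arclength"

    def __post_init__(self) -> None:
        object.__setattr__(self, "points", tuple(self.points))

    @property
    def max_volume(self) -> float:
        """Volume of the R = 1 rung at the global maximum deviation."""
        return self.points[0].volume


def pointwise_deviations(standard: Path3D, repetitions: RepetitionSet) -> DeviationMatrix:
    """Euclidean deviation of every repetition point from its standard point.

    All paths must share a common length ``N`` (index-aligned comparison —
    there is no elastic time warping in this metric).
    """
    n = len(standard)
    for p in repetitions.repetitions:
        if len(p) != n:
            raise AlignmentError(
                f"repetition {p.label!r} has {len(p)} points but the standard has "
                f"{n}; resample all paths to a common length first"
            )
    stack = np.stack([p.points for p in repetitions.repetitions])  # (M, N, 3)
    return DeviationMatrix(np.linalg.norm(stack - standard.points[None], axis=2))


def threshold_ladder(dev: DeviationMatrix, origin: LadderOrigin = "maxima") -> ThresholdLadder:
    """Build the descending ladder of candidate tolerance radii.

    ``origin="full"`` uses the whole M*N deviation multiset; ``"maxima"``
    uses only the distinct per-repetition maxima.  The maxima ladder is
    lossless for reliability: a repetition conforms at radius d exactly when
    its maximum deviation is <= d, so R(d) can only change at a per-path
    maximum.
    """
    if origin == "full":
        pool = dev.values.ravel()
    elif origin == "maxima":
        pool = dev.per_path_max
    else:
        raise DomainError(f"unknown ladder origin {origin!r}")
    return ThresholdLadder(np.unique(pool)[::-1].copy(), origin=origin)


def tube_volume(d: float, h: float) -> float:
    """Volume (cm^3) of a tube of radius ``d`` around a path of length ``h``."""
    if d < 0:
        raise DomainError(f"tube radius must be non-negative, got {d}")
    if h <= 0:
        raise DomainError(f"tube length must be positive, got {h}")
    return math.pi * d * d * h


def reliability_at_threshold(dev: DeviationMatrix, d_j: float) -> tuple[float, int]:
    """Fraction of repetitions fully contained in the radius-``d_j`` tube.

    A repetition conforms iff every one of its pointwise deviations is at
    most ``d_j`` — equivalently, its maximum deviation is at most ``d_j``.
    Returns ``(n/M, n)`` where ``n`` counts conforming repetitions.
    """
    if d_j < 0:
        raise DomainError(f"threshold must be non-negative, got {d_j}")
    n = int(np.count_nonzero(dev.per_path_max <= d_j))
    return n / dev.M, n


def _resolve_h(standard: Path3D, h_mode: HMode, fixed_h: float | None) -> float:
    if h_mode == "arclength":
        return arc_length(standard)
    if h_mode == "fixed":
        if fixed_h is None:
            raise DomainError("h_mode='fixed' requires fixed_h")
        if fixed_h <= 0:
            raise DomainError(f"fixed_h must be positive, got {fixed_h}")
        return float(fixed_h)
    raise DomainError(f"unknown h_mode {h_mode!r}")


def compute_rv_curve(
    standard: Path3D,
    repetitions: RepetitionSet,
    h_mode: HMode = "arclength",
    fixed_h: float | None = None,
    ladder_origin: LadderOrigin = "maxima",
) -> RVCurve:
    """Compute the full RV curve for a prepared repetition set.

    For each ladder rung ``d_j`` (descending) the curve records the tube
    volume ``pi d_j^2 h`` and the empirical reliability ``n_j / M``.  ``h``
    is the standard path's arc length by default, or a fixed workspace
    height (e.g. the 2 cm of a cylindrical training workspace) when
    ``h_mode="fixed"``.
    """
    dev = pointwise_deviations(standard, repetitions)
    ladder = threshold_ladder(dev, ladder_origin)
    h = _resolve_h(standard, h_mode, fixed_h)
    pts = []
    for d_j in ladder.thresholds:
        r, n = reliability_at_threshold(dev, d_j)
        pts.append(RVPoint(float(d_j), tube_volume(float(d_j), h), r, n))
    return RVCurve(tuple(pts), h=h, M=repetitions.M, h_mode=h_mode)


def volume_at_reliability(curve: RVCurve, r_target: float) -> float:
    """Smallest tube volume on the curve achieving reliability >= ``r_target``.

    Because the attainable reliabilities are multiples of 1/M, a target of
    0.95 with fewer than 20 repetitions effectively requires every
    repetition to conform.  The largest rung always has R = 1, so a result
    exists for any target in (0, 1].
    """
    if not 0.0 < r_target <= 1.0:
        raise DomainError(f"reliability target must lie in (0, 1], got {r_target}")
    qualifying = [p.volume for p in curve.points if p.reliability >= r_target]
    return min(qualifying)


def conventional_working_volume(repetitions: RepetitionSet) -> float:
    """Mean spherical working volume across repetitions (cm^3).

    Per repetition the sphere radius is the mean Euclidean distance of the
    path's points from the path's own centroid; the volumes
    ``(4/3) pi r^3`` are averaged arithmetically across repetitions.  This
    is the average-based baseline the tube-based RV volume is compared
    against: it ignores the standard path entirely.
    """
    vols = []
    for p in repetitions.repetitions:
        centroid = p.points.mean(axis=0)
        r_bar = float(np.linalg.norm(p.points - centroid, axis=1).mean())
        if r_bar == 0.0:
            logger.warning("repetition %r: all points coincident, working volume 0", p.label)
        vols.append(4.0 / 3.0 * math.pi * r_bar**3)
    return float(np.mean(vols))
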