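"""Synthetic standard paths and repetition ensembles with known statistics.

Real knot-tying recordings are not redistributable, so every pipeline
stage is exercised against generated data whose statistical structure is
known exactly.  The generator emulates the task geometry with a two-loop
helix (the suture is wound twice around the instrument) and perturbs each
repetition point with independent isotropic Gaussian noise of per-axis
scale ``sigma_m``.  Three noise schedules model training conditions:

* ``flat`` — constant variability, a trainee at steady state;
* ``learning`` — sigma halves geometrically across the series, modelling
  precision gains with practice;
* ``fatigue`` — constant sigma with one episodic spike (default x3 over
  5 consecutive repetitions), modelling transient fatigue or distraction.

Under isotropic noise the pointwise deviation is sigma times a
chi-distributed variable with 3 degrees of freedom, which yields a closed
form for the probability that a whole repetition of N points stays inside
a radius-d tube: ``[F_chi3(d / sigma)]**N``.  That closed form is the
independent oracle against which the empirical reliability estimator is
validated, and its mean (``sigma * 2 * sqrt(2/pi)``) gives a method-of-
moments estimator recovering sigma from a deviation matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.stats import chi

from .errors import DomainError, EmptyInputError
from .paths import Path3D, RepetitionSet, resample_by_arclength
from .rv import DeviationMatrix

__all__ = [
    "NoiseProfile",
    "SimulationConfig",
    "flat_profile",
    "learning_profile",
    "fatigue_profile",
    "make_standard_path",
    "simulate_repetitions",
    "simulate",
    "analytic_reliability",
    "estimate_sigma",
]

PathKind = Literal["helix", "circle", "line"]

#: chi(3) mean factor: E[chi_3] = 2 * sqrt(2 / pi)
_CHI3_MEAN = 2.0 * np.sqrt(2.0 / np.pi)

DEFAULT_N_POINTS = 200
DEFAULT_N_REPS = 50
DEFAULT_SIGMA = 0.8  # cm; places simulated tube volumes in the few-hundred cm^3 range
HELIX_PITCH_RATIO = 0.3  # pitch per loop, as a fraction of the helix radius


@dataclass(frozen=True)
class NoiseProfile:
    """Per-repetition noise scales sigma_m (cm) plus the RNG seed."""

    sigma_schedule: np.ndarray
    kind: Literal["flat", "learning", "fatigue"]
    seed: int

    def __post_init__(self) -> None:
        s = np.asarray(self.sigma_schedule, dtype=float)
        if s.ndim != 1 or s.size == 0:
            raise DomainError("sigma schedule must be a non-empty 1D array")
        if np.any(s <= 0) or not np.all(np.isfinite(s)):
            raise DomainError("all sigma_m must be positive and finite")
        object.__setattr__(self, "sigma_schedule", s)

    @property
    def n_reps(self) -> int:
        return self.sigma_schedule.size


@dataclass(frozen=True)
class SimulationConfig:
    n_points: int = DEFAULT_N_POINTS
    n_reps: int = DEFAULT_N_REPS
    path_kind: PathKind = "helix"
    path_scale: float = 1.0
    profile: NoiseProfile | None = None

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise DomainError("n_points must be >= 2")
        if self.n_reps < 1:
            raise DomainError("n_reps must be >= 1")


def flat_profile(sigma: float = DEFAULT_SIGMA, n_reps: int = DEFAULT_N_REPS, seed: int = 0) -> NoiseProfile:
    """Constant noise scale across all repetitions."""
    if sigma <= 0:
        raise DomainError("sigma must be positive")
    return NoiseProfile(np.full(n_reps, float(sigma)), "flat", seed)


def learning_profile(
    sigma_start: float = DEFAULT_SIGMA,
    n_reps: int = DEFAULT_N_REPS,
    seed: int = 0,
    sigma_end: float | None = None,
) -> NoiseProfile:
    """Noise scale decaying geometrically from ``sigma_start`` to ``sigma_end``.

    The default end point is half the start — variability halves over the
    training series as precision improves.
    """
    if sigma_start <= 0:
        raise DomainError("sigma_start must be positive")
    end = sigma_start / 2.0 if sigma_end is None else float(sigma_end)
    if end <= 0:
        raise DomainError("sigma_end must be positive")
    if n_reps == 1:
        schedule = np.array([sigma_start])
    else:
        schedule = sigma_start * (end / sigma_start) ** (np.arange(n_reps) / (n_reps - 1))
    return NoiseProfile(schedule, "learning", seed)


def fatigue_profile(
    sigma: float = DEFAULT_SIGMA,
    n_reps: int = DEFAULT_N_REPS,
    seed: int = 0,
    spike_start: int | None = None,
    spike_length: int = 5,
    spike_factor: float = 3.0,
) -> NoiseProfile:
    """Flat noise with one episodic spike of elevated variability.

    ``spike_start`` is 1-based; the default places the spike just past the
    midpoint of the series (repetition 26 of 50), so checkpoints before it
    see steady-state behaviour.
    """
    if sigma <= 0 or spike_factor <= 0:
        raise DomainError("sigma and spike_factor must be positive")
    if spike_length < 1:
        raise DomainError("spike_length must be >= 1")
    start = (n_reps // 2) + 1 if spike_start is None else int(spike_start)
    if not 1 <= start <= n_reps:
        raise DomainError(f"spike_start {start} outside 1..{n_reps}")
    schedule = np.full(n_reps, float(sigma))
    schedule[start - 1 : start - 1 + spike_length] *= spike_factor
    return NoiseProfile(schedule, "fatigue", seed)


def make_standard_path(
    kind: PathKind = "helix", scale: float = 1.0, n_points: int = DEFAULT_N_POINTS
) -> Path3D:
    """Deterministic parametric reference curve, arc-length-uniform.

    * ``helix`` — two full loops (4 pi radians) of radius ``scale`` cm with
      a small pitch (0.3 cm per loop at unit scale), emulating a suture
      wound twice around an instrument;
    * ``circle`` — one loop of radius ``scale`` in the xy-plane;
    * ``line`` — a straight segment of length ``scale`` along z.

    The curve is sampled densely and then resampled at ``n_points`` equal
    arc-length increments, so consecutive points are equidistant along the
    geometry.
    """
    if n_points < 2:
        raise DomainError("n_points must be >= 2")
    if scale <= 0:
        raise DomainError("scale must be positive")
    if kind == "line":
        dense = np.column_stack(
            [np.zeros(2), np.zeros(2), np.array([0.0, scale])]
        )
    elif kind == "circle":
        theta = np.linspace(0.0, 2.0 * np.pi, max(20 * n_points, 1000))
        dense = np.column_stack(
            [scale * np.cos(theta), scale * np.sin(theta), np.zeros_like(theta)]
        )
    elif kind == "helix":
        theta = np.linspace(0.0, 4.0 * np.pi, max(20 * n_points, 1000))
        pitch = HELIX_PITCH_RATIO * scale
        dense = np.column_stack(
            [
                scale * np.cos(theta),
                scale * np.sin(theta),
                pitch * theta / (2.0 * np.pi),
            ]
        )
    else:
        raise DomainError(f"unknown path kind {kind!r}")
    return resample_by_arclength(Path3D(dense, label=kind), n_points)


def simulate_repetitions(standard: Path3D, profile: NoiseProfile) -> RepetitionSet:
    """Perturb the standard path once per repetition with isotropic noise.

    Repetition ``m`` adds independent N(0, sigma_m^2) noise to each
    coordinate of each point.  All randomness flows through one
    ``numpy.random.default_rng(profile.seed)`` generator, so a fixed seed
    reproduces coordinates exactly.
    """
    rng = np.random.default_rng(profile.seed)
    n = len(standard)
    reps = []
    for m, sigma in enumerate(profile.sigma_schedule, start=1):
        noise = rng.normal(0.0, sigma, size=(n, 3))
        reps.append(Path3D(standard.points + noise, label=f"rep{m:03d}"))
    return RepetitionSet(standard, tuple(reps), n)


def simulate(config: SimulationConfig) -> RepetitionSet:
    """Convenience wrapper: build the standard path and its repetitions."""
    profile = config.profile if config.profile is not None else flat_profile(n_reps=config.n_reps)
    if profile.n_reps != config.n_reps:
        raise DomainError(
            f"profile covers {profile.n_reps} repetitions, config requests {config.n_reps}"
        )
    std = make_standard_path(config.path_kind, config.path_scale, config.n_points)
    return simulate_repetitions(std, profile)


def analytic_reliability(d: float, sigma: float, n_points: int) -> float:
    """Closed-form tube-containment probability under isotropic noise.

    Each pointwise deviation is sigma * chi_3; a repetition of ``n_points``
    independent points stays inside the radius-``d`` tube with probability
    ``F_chi3(d / sigma) ** n_points``.
    """
    if d < 0:
        raise DomainError("d must be non-negative")
    if sigma <= 0:
        raise DomainError("sigma must be positive")
    if n_points < 1:
        raise DomainError("n_points must be >= 1")
    return float(chi(3).cdf(d / sigma) ** n_points)


def estimate_sigma(dev: DeviationMatrix) -> float:
    """Method-of-moments noise-scale estimate from a deviation matrix.

    Valid for flat profiles: the mean of sigma * chi_3 is
    sigma * 2 * sqrt(2/pi), so the estimator is the grand mean deviation
    divided by that factor.
    """
    if dev.values.size == 0:
        raise EmptyInputError("empty deviation matrix")
    return float(dev.values.mean() / _CHI3_MEAN)
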