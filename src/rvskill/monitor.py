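"""Monitoring skill evolution across a repetitive training series.

The RV curve of the first ``m`` repetitions (a *prefix window*) shows how
skill evolves as training accumulates.  Two complementary traces are
tracked at checkpoints (by default repetitions 10, 25 and 50):

* reliability at a fixed tube volume — sensitive to fatigue or distraction,
  which show up as drops in the success fraction;
* tube volume at a fixed reliability target (default R = 0.95) — sensitive
  to precision gains, which show up as shrinking volume.

A simple closed-loop stopping rule operates on the reliability trace:
when the success fraction at the fixed volume changes by at least a
threshold (default ``|dR| >= 0.05``) between consecutive checkpoints,
training pauses and skill is read from the *last stable point* — the
checkpoint immediately preceding the change.  The rule is triggered by
the absolute change, so a sudden improvement pauses training just like a
sudden decline: either signals that performance is no longer stable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import DomainError, InsufficientDataError
from .paths import Path3D, RepetitionSet
from .rv import (
    HMode,
    RVCurve,
    _resolve_h,
    compute_rv_curve,
    pointwise_deviations,
    volume_at_reliability,
)

__all__ = [
    "MonitorTrace",
    "StoppingDecision",
    "prefix_rv",
    "reliability_trace",
    "volume_trace",
    "apply_stopping_rule",
]

DEFAULT_CHECKPOINTS = (10, 25, 50)
DEFAULT_DELTA_R = 0.05


@dataclass(frozen=True)
class MonitorTrace:
    """Reliability (or volume) evaluated at increasing repetition counts.

    Exactly one of ``fixed_volume`` (cm^3, reliability tracked) or
    ``fixed_reliability`` (volume tracked) must be set.
    """

    checkpoints: tuple[int, ...]
    values: tuple[float, ...]
    fixed_volume: float | None = None
    fixed_reliability: float | None = None

    def __post_init__(self) -> None:
        cps = tuple(int(c) for c in self.checkpoints)
        vals = tuple(float(v) for v in self.values)
        if len(cps) == 0:
            raise InsufficientDataError("trace has no checkpoints")
        if any(b <= a for a, b in zip(cps, cps[1:])):
            raise DomainError(f"checkpoints must be strictly increasing, got {cps}")
        if len(vals) != len(cps):
            raise DomainError("one value per checkpoint required")
        if (self.fixed_volume is None) == (self.fixed_reliability is None):
            raise DomainError(
                "exactly one of fixed_volume / fixed_reliability must be set"
            )
        object.__setattr__(self, "checkpoints", cps)
        object.__setattr__(self, "values", vals)

    @property
    def tracks_reliability(self) -> bool:
        return self.fixed_volume is not None


@dataclass(frozen=True)
class StoppingDecision:
    """Outcome of the |dR| stopping rule on a reliability trace.

    When triggered, ``stop_checkpoint`` is the last stable measurement —
    the checkpoint immediately preceding the first change of magnitude
    at least the threshold — and ``delta_r`` is that (signed) change.
    """

    triggered: bool
    trigger_checkpoint: int | None = None
    stop_checkpoint: int | None = None
    delta_r: float | None = None


def prefix_rv(
    standard: Path3D,
    repetitions: RepetitionSet,
    m: int,
    h_mode: HMode = "arclength",
    fixed_h: float | None = None,
) -> RVCurve:
    """RV curve computed on training repetitions ``1..m`` only."""
    return compute_rv_curve(standard, repetitions.prefix(m), h_mode, fixed_h)


def _check_checkpoints(checkpoints: Sequence[int], M: int) -> tuple[int, ...]:
    cps = tuple(int(c) for c in checkpoints)
    for c in cps:
        if not 1 <= c <= M:
            raise DomainError(f"checkpoint {c} outside the recorded 1..{M} repetitions")
    return cps


def reliability_trace(
    standard: Path3D,
    repetitions: RepetitionSet,
    checkpoints: Sequence[int] = DEFAULT_CHECKPOINTS,
    *,
    fixed_volume: float,
    h_mode: HMode = "arclength",
    fixed_h: float | None = None,
) -> MonitorTrace:
    """Reliability at a fixed tube volume, per prefix checkpoint.

    The fixed volume implies a tube radius ``d = sqrt(V / (pi h))``; at
    checkpoint ``m`` the value is ``n/m`` where ``n`` counts repetitions
    among the first ``m`` whose maximum deviation is at most ``d``.
    """
    if fixed_volume <= 0:
        raise DomainError(f"fixed_volume must be positive, got {fixed_volume}")
    cps = _check_checkpoints(checkpoints, repetitions.M)
    h = _resolve_h(standard, h_mode, fixed_h)
    d = math.sqrt(fixed_volume / (math.pi * h))
    maxima = pointwise_deviations(standard, repetitions).per_path_max
    values = tuple(float(np.count_nonzero(maxima[:m] <= d)) / m for m in cps)
    return MonitorTrace(cps, values, fixed_volume=fixed_volume)


def volume_trace(
    standard: Path3D,
    repetitions: RepetitionSet,
    checkpoints: Sequence[int] = DEFAULT_CHECKPOINTS,
    r_target: float = 0.95,
    h_mode: HMode = "arclength",
    fixed_h: float | None = None,
) -> MonitorTrace:
    """Smallest tube volume reaching ``r_target`` reliability, per checkpoint."""
    cps = _check_checkpoints(checkpoints, repetitions.M)
    values = tuple(
        volume_at_reliability(prefix_rv(standard, repetitions, m, h_mode, fixed_h), r_target)
        for m in cps
    )
    return MonitorTrace(cps, values, fixed_reliability=r_target)


def apply_stopping_rule(
    trace: MonitorTrace, delta_threshold: float = DEFAULT_DELTA_R
) -> StoppingDecision:
    """First-trigger |dR| rule over consecutive checkpoint pairs.

    Scans checkpoint pairs in order; the first pair whose reliability
    change has magnitude at least ``delta_threshold`` triggers, and
    training stops at the earlier member of that pair (the last stable
    measurement).  If no pair triggers, training continues.
    """
    if not trace.tracks_reliability:
        raise DomainError("the stopping rule operates on a reliability trace at fixed volume")
    if len(trace.checkpoints) < 2:
        raise InsufficientDataError("the stopping rule needs at least 2 checkpoints")
    if delta_threshold <= 0:
        raise DomainError(f"delta threshold must be positive, got {delta_threshold}")
    for (c0, c1), (r0, r1) in zip(
        zip(trace.checkpoints, trace.checkpoints[1:]),
        zip(trace.values, trace.values[1:]),
    ):
        delta = r1 - r0
        # small tolerance so printed two-decimal reliabilities compare exactly
        if abs(delta) >= delta_threshold - 1e-12:
            return StoppingDecision(
                triggered=True,
                trigger_checkpoint=c1,
                stop_checkpoint=c0,
                delta_r=delta,
            )
    return StoppingDecision(triggered=False)
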