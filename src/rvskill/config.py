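"""Run configuration shared by the CLI commands.

Defaults follow the training-workspace conventions the metric was designed
around: tube length from the standard path's arc length (with a 2 cm fixed
workspace height available as the alternative), a reliability target of
0.95 for precision tracking, a stopping threshold of |dR| = 0.05, and
checkpoints at repetitions 10, 25 and 50.  A YAML config file may set any
field; command-line flags override file values.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import yaml

from .errors import DomainError

__all__ = ["RunConfig", "load_config"]


@dataclass(frozen=True)
class RunConfig:
    h_mode: str = "arclength"
    fixed_h: float = 2.0
    r_target: float = 0.95
    delta_r: float = 0.05
    checkpoints: tuple[int, ...] = (10, 25, 50)
    n_resample: int | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.h_mode not in ("arclength", "fixed"):
            raise DomainError(f"h_mode must be 'arclength' or 'fixed', got {self.h_mode!r}")
        if self.fixed_h <= 0:
            raise DomainError("fixed_h must be positive")
        if not 0 < self.r_target <= 1:
            raise DomainError("r_target must lie in (0, 1]")
        if self.delta_r <= 0:
            raise DomainError("delta_r must be positive")
        object.__setattr__(self, "checkpoints", tuple(int(c) for c in self.checkpoints))

    def digest(self) -> str:
        """Short stable hash of the configuration, for run logs."""
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def override(self, **kwargs) -> "RunConfig":
        """New config with the given non-None fields replaced."""
        updates = {k: v for k, v in kwargs.items() if v is not None}
        return replace(self, **updates)


def load_config(path: str | Path | None) -> RunConfig:
    """Build a RunConfig from a YAML file (or defaults when path is None)."""
    if path is None:
        return RunConfig()
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise DomainError(f"{path}: config file must contain a mapping")
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise DomainError(f"{path}: unknown config keys {sorted(unknown)}")
    return RunConfig(**raw)
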