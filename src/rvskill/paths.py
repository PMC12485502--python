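"""Reading, validating and resampling 3D instrument paths.

A recording session yields one *standard* path (the expert reference) and
``M`` training repetitions, all stored as plain-text tables with columns
``rep_id, frame, x, y, z`` (coordinates in centimetres).  Pointwise
comparison requires every path to carry the same number of points, so this
module also provides arc-length resampling: each path is re-indexed at equal
distances along its own piecewise-linear geometry, which preserves the shape
while normalising the sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    AlignmentError,
    DegeneratePathError,
    EmptyInputError,
    FormatError,
    ParseError,
)

__all__ = [
    "Path3D",
    "RepetitionSet",
    "read_paths",
    "write_paths",
    "build_repetition_set",
    "arc_length",
    "resample_by_arclength",
    "write_rv_table",
    "read_rv_table",
]

#: Column names expected in trajectory tables.
TRAJECTORY_COLUMNS = ("rep_id", "frame", "x", "y", "z")

#: Reserved repetition id identifying the standard path inside a mixed table.
STANDARD_ID = "standard"


@dataclass(frozen=True)
class Path3D:
    """An ordered sequence of 3D points (centimetres) from one recording.

    Parameters
    ----------
    points
        Array of shape ``(n, 3)`` with ``n >= 2``; all coordinates finite.
    label
        Free-text identifier (repetition id or file stem).
    source_index
        Original frame indices, if the path came from a recording. ``None``
        for synthetic or resampled paths.
    """

    points: np.ndarray
    label: str = ""
    source_index: np.ndarray | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise DegeneratePathError(
                f"path {self.label!r}: expected an (n, 3) array, got shape {pts.shape}"
            )
        if pts.shape[0] < 2:
            raise DegeneratePathError(
                f"path {self.label!r}: needs at least 2 points, got {pts.shape[0]}"
            )
        if not np.all(np.isfinite(pts)):
            raise DegeneratePathError(f"path {self.label!r}: non-finite coordinates")
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return self.points.shape[0]


@dataclass(frozen=True)
class RepetitionSet:
    """A standard path plus ``M`` training repetitions sharing one length.

    The invariant that every contained path has exactly ``common_length``
    points is what makes the pointwise deviation matrix well defined.
    """

    standard: Path3D
    repetitions: tuple[Path3D, ...]
    common_length: int

    def __post_init__(self) -> None:
        reps = tuple(self.repetitions)
        if len(reps) < 1:
            raise EmptyInputError("a RepetitionSet needs at least one repetition")
        for p in (self.standard, *reps):
            if len(p) != self.common_length:
                raise AlignmentError(
                    f"path {p.label!r} has {len(p)} points, expected "
                    f"{self.common_length}; resample all paths to a common length"
                )
        object.__setattr__(self, "repetitions", reps)

    @property
    def M(self) -> int:
        """Number of training repetitions."""
        return len(self.repetitions)

    @property
    def N(self) -> int:
        """Common point count."""
        return self.common_length

    def prefix(self, m: int) -> "RepetitionSet":
        """The sub-set holding only repetitions ``1..m`` (training order)."""
        from .errors import DomainError

        if not 1 <= m <= self.M:
            raise DomainError(f"prefix count m={m} outside 1..{self.M}")
        return RepetitionSet(self.standard, self.repetitions[:m], self.common_length)


def _coerce_numeric(df: pd.DataFrame, column: str, source: str) -> pd.Series:
    converted = pd.to_numeric(df[column], errors="coerce")
    bad = converted.isna() & df[column].notna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ParseError(
            f"{source}: non-numeric value {df[column].iloc[row]!r} in column "
            f"{column!r} at data row {row + 1}"
        )
    if converted.isna().any():
        row = int(np.flatnonzero(converted.isna().to_numpy())[0])
        raise ParseError(f"{source}: missing value in column {column!r} at data row {row + 1}")
    return converted


def _paths_from_frame(df: pd.DataFrame, grouping: str, source: str) -> dict[str, Path3D]:
    if df.empty:
        raise EmptyInputError(f"{source}: table contains no data rows")
    for col in (grouping, "frame", "x", "y", "z"):
        if col not in df.columns:
            raise FormatError(f"{source}: missing required column {col!r}")
    frame = _coerce_numeric(df, "frame", source)
    coords = np.column_stack([_coerce_numeric(df, c, source) for c in ("x", "y", "z")])
    out: dict[str, Path3D] = {}
    # groupby(sort=False) keeps first-appearance order; the stable sort on the
    # frame column preserves file order among tied frame values.
    for rep_id, idx in df.groupby(df[grouping].astype(str), sort=False).indices.items():
        order = idx[np.argsort(frame.to_numpy()[idx], kind="stable")]
        out[rep_id] = Path3D(
            coords[order], label=str(rep_id), source_index=frame.to_numpy()[order]
        )
    return out


def read_paths(source: str | Path, grouping: str = "rep_id") -> dict[str, Path3D]:
    """Read one or many paths from a CSV file or a directory of CSV files.

    A single file must carry the ``grouping`` column (default ``rep_id``);
    each distinct id becomes one :class:`Path3D`, points ordered by frame.
    For a directory, every ``*.csv`` inside is read and the file stem is used
    as the repetition id (the grouping column is then optional per file).

    Returns a dict keyed by repetition id, in order of first appearance
    (file order for a single table, sorted file names for a directory).
    """
    source = Path(source)
    if source.is_dir():
        out: dict[str, Path3D] = {}
        files = sorted(source.glob("*.csv"))
        if not files:
            raise EmptyInputError(f"{source}: directory contains no CSV files")
        for f in files:
            df = pd.read_csv(f)
            if grouping not in df.columns:
                df[grouping] = f.stem
            sub = _paths_from_frame(df, grouping, str(f))
            for rep_id, p in sub.items():
                key = rep_id if len(sub) > 1 else f.stem
                out[key] = Path3D(p.points, label=key, source_index=p.source_index)
        return out
    try:
        df = pd.read_csv(source)
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{source}: table contains no data rows") from None
    return _paths_from_frame(df, grouping, str(source))


def write_paths(paths: Mapping[str, Path3D] | Iterable[Path3D], destination: str | Path) -> None:
    """Write paths to one CSV with columns ``rep_id, frame, x, y, z``."""
    if isinstance(paths, Mapping):
        items = list(paths.items())
    else:
        items = [(p.label, p) for p in paths]
    frames = []
    for rep_id, p in items:
        idx = p.source_index if p.source_index is not None else np.arange(len(p))
        frames.append(
            pd.DataFrame(
                {
                    "rep_id": rep_id,
                    "frame": np.asarray(idx),
                    "x": p.points[:, 0],
                    "y": p.points[:, 1],
                    "z": p.points[:, 2],
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(destination, index=False)


def arc_length(path: Path3D) -> float:
    """Total length (cm) of the piecewise-linear path.

    The sum of Euclidean lengths of consecutive point-to-point segments;
    for a densely sampled smooth curve this chord sum converges to the true
    arc length.
    """
    if len(path) < 2:
        raise DegeneratePathError("arc length needs at least 2 points")
    return float(np.linalg.norm(np.diff(path.points, axis=0), axis=1).sum())


def resample_by_arclength(path: Path3D, n_points: int) -> Path3D:
    """Resample a path at ``n_points`` equal arc-length increments.

    Endpoints are preserved exactly; interior points are placed by linear
    interpolation along the polyline. Raises
    :class:`~rvskill.errors.DegeneratePathError` when all input points
    coincide (zero total arc length).
    """
    if n_points < 2:
        raise DegeneratePathError(f"n_points must be >= 2, got {n_points}")
    pts = path.points
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    if total <= 0.0:
        raise DegeneratePathError(
            f"path {path.label!r}: zero total arc length (all points coincident)"
        )
    targets = np.linspace(0.0, total, n_points)
    new = np.column_stack([np.interp(targets, cum, pts[:, k]) for k in range(3)])
    new[0] = pts[0]
    new[-1] = pts[-1]
    return Path3D(new, label=path.label)


def build_repetition_set(
    standard: Path3D,
    repetitions: Sequence[Path3D],
    n_points: int | None = None,
) -> RepetitionSet:
    """Resample standard and repetitions to a shared length and bundle them.

    ``n_points`` defaults to the standard path's own point count; pass an
    explicit value to normalise everything to a configured resolution.
    """
    if len(repetitions) == 0:
        raise EmptyInputError("need at least one training repetition")
    n = int(n_points) if n_points is not None else len(standard)
    std = standard if len(standard) == n else resample_by_arclength(standard, n)
    reps = tuple(p if len(p) == n else resample_by_arclength(p, n) for p in repetitions)
    return RepetitionSet(std, reps, n)


def write_rv_table(curve, destination: str | Path) -> None:
    """Write an RV curve as CSV ``d_cm, volume_cm3, reliability, n_success``.

    Rows are ordered by descending threshold radius, matching the curve.
    """
    if len(curve.points) == 0:
        raise EmptyInputError("cannot write an empty RV curve")
    df = pd.DataFrame(
        {
            "d_cm": [p.d for p in curve.points],
            "volume_cm3": [p.volume for p in curve.points],
            "reliability": [p.reliability for p in curve.points],
            "n_success": [p.n_success for p in curve.points],
        }
    )
    df.to_csv(destination, index=False, float_format="%.9g")


def read_rv_table(source: str | Path) -> pd.DataFrame:
    """Read back a table written by :func:`write_rv_table`."""
    df = pd.read_csv(source)
    for col in ("d_cm", "volume_cm3", "reliability", "n_success"):
        if col not in df.columns:
            raise FormatError(f"{source}: missing required column {col!r}")
    return df
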