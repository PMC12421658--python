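"""Replica alignment and the mean ± SD summary behind every line plot.

A *replica* is one independent repetition of a simulation condition.
All time-dependent analyses report, per timepoint, the arithmetic mean
across replicas together with the sample standard deviation (n-1
denominator); with a single replica the band is identically zero.
Descriptive statistics only — no confidence intervals or tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import AlignmentError, UnitError, ValidationError
from .gromacs_io import TimeSeries

__all__ = ["ReplicaSet", "SummaryTrace", "align_replicas", "summarize", "to_nanoseconds"]


@dataclass
class ReplicaSet:
    """One simulation group's replicas of a single property."""

    group_label: str
    series: list[TimeSeries]

    def __post_init__(self) -> None:
        if not self.series:
            raise ValidationError(f"group {self.group_label!r} has no replicas")
        names = {s.property_name for s in self.series}
        if len(names) > 1:
            raise ValidationError(
                f"group {self.group_label!r} mixes properties {sorted(names)}"
            )

    @property
    def n_replicas(self) -> int:
        return len(self.series)


@dataclass
class SummaryTrace:
    """Per-timepoint mean and standard deviation of one replica group.

    ``axis`` is simulation time (ns) for temporal properties, or the
    residue/atom index for per-residue profiles such as RMSF.
    """

    axis: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    n_replicas: int
    group_label: str = ""
    axis_name: str = "time (ns)"

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        if not (len(self.axis) == len(self.mean) == len(self.sd)):
            raise ValidationError("SummaryTrace vectors must share one length")
        if np.any(self.sd < 0):
            raise ValidationError("SummaryTrace sd must be non-negative")
        if self.n_replicas < 1:
            raise ValidationError("SummaryTrace requires n_replicas >= 1")


def to_nanoseconds(ts: TimeSeries) -> TimeSeries:
    """Convert a time axis to nanoseconds (GROMACS writes ps by default)."""
    if ts.time_unit == "ns":
        return ts
    if ts.time_unit == "ps":
        return TimeSeries(
            time=ts.time / 1000.0,
            values=ts.values,
            property_name=ts.property_name,
            replica_id=ts.replica_id,
            time_unit="ns",
        )
    raise UnitError(f"unknown time unit {ts.time_unit!r} (expected ps or ns)")


def to_picoseconds(ts: TimeSeries) -> TimeSeries:
    """Inverse of :func:`to_nanoseconds`, used in round-trip tests."""
    if ts.time_unit == "ps":
        return ts
    if ts.time_unit == "ns":
        return TimeSeries(
            time=ts.time * 1000.0,
            values=ts.values,
            property_name=ts.property_name,
            replica_id=ts.replica_id,
            time_unit="ps",
        )
    raise UnitError(f"unknown time unit {ts.time_unit!r} (expected ps or ns)")


def _median_step(t: np.ndarray) -> float:
    return float(np.median(np.diff(t))) if len(t) > 1 else 1.0


def align_replicas(rs: ReplicaSet, rel_tol: float = 0.01) -> ReplicaSet:
    """Put all replicas of a group onto one common axis.

    If every replica's axis matches the first replica's pointwise to
    within ``rel_tol`` of the sampling interval (after truncating to the
    shortest series), the first replica's axis is adopted.  Otherwise
    all series are truncated to the overlapping time range and resampled
    onto the coarsest replica's grid by nearest-neighbour lookup —
    deliberately interpolation-free so summary values remain actual
    simulation samples.
    """
    if rs.n_replicas == 1:
        return rs

    n_min = min(len(s) for s in rs.series)
    ref = rs.series[0].time[:n_min]
    step = _median_step(ref)
    tol = rel_tol * step
    if all(np.all(np.abs(s.time[:n_min] - ref) <= tol) for s in rs.series):
        out = [
            TimeSeries(ref, s.values[:n_min], s.property_name, s.replica_id, s.time_unit)
            for s in rs.series
        ]
        return ReplicaSet(rs.group_label, out)

    lo = max(s.time[0] for s in rs.series)
    hi = min(s.time[-1] for s in rs.series)
    if lo > hi:
        bad = ", ".join(s.replica_id or f"replica {i}" for i, s in enumerate(rs.series))
        raise AlignmentError(
            f"group {rs.group_label!r}: replica time axes do not overlap ({bad})"
        )
    # coarsest grid = largest median step
    coarsest = max(rs.series, key=lambda s: _median_step(s.time))
    mask = (coarsest.time >= lo) & (coarsest.time <= hi)
    grid = coarsest.time[mask]
    if len(grid) == 0:
        raise AlignmentError(
            f"group {rs.group_label!r}: overlapping range [{lo}, {hi}] holds no samples"
        )
    out = []
    for s in rs.series:
        idx = np.searchsorted(s.time, grid)
        idx = np.clip(idx, 1, len(s.time) - 1)
        left = s.time[idx - 1]
        right = s.time[idx]
        choose_left = (grid - left) <= (right - grid)
        nearest = np.where(choose_left, idx - 1, idx)
        out.append(
            TimeSeries(grid, s.values[nearest], s.property_name, s.replica_id, s.time_unit)
        )
    return ReplicaSet(rs.group_label, out)


def summarize(rs: ReplicaSet, axis_name: str = "time (ns)") -> SummaryTrace:
    """Arithmetic mean and sample SD across replicas at every timepoint.

    Replicas must already share one axis (see :func:`align_replicas`).
    With a single replica the SD is identically zero.
    """
    ref = rs.series[0].time
    for s in rs.series[1:]:
        if len(s.time) != len(ref) or not np.array_equal(s.time, ref):
            raise ValidationError(
                f"group {rs.group_label!r}: replica axes differ; "
                "run align_replicas first"
            )
    stacked = np.vstack([s.values for s in rs.series])
    mean = stacked.mean(axis=0)
    if rs.n_replicas == 1:
        sd = np.zeros_like(mean)
    else:
        sd = stacked.std(axis=0, ddof=1)
    return SummaryTrace(
        axis=ref,
        mean=mean,
        sd=sd,
        n_replicas=rs.n_replicas,
        group_label=rs.group_label,
        axis_name=axis_name,
    )
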