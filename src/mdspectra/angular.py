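"""Circular statistics for dihedral angles.

Dihedral angles are periodic (0° ≡ 360°), so naive arithmetic means are
wrong near the wrap point: the average of 10° and 350° is 0°, not 180°.
Directions are averaged on the unit circle,

    mean = atan2( mean(sin θ_i), mean(cos θ_i) )

with the resultant length R = |mean unit vector| measuring concentration.
R ≈ 0 (e.g. {0°, 180°}) leaves the mean direction undefined; that case
yields an explicit NaN-plus-warning signal, never a silent 0.

All angles live on the canonical interval [-180°, 180°), matching
``gmx angle``/``gmx rama``/``gmx chi`` output and Ramachandran axes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ValidationError

__all__ = [
    "AngleSeries",
    "wrap_angle",
    "circular_mean",
    "circular_mean_trace",
    "concat_replicas",
    "time_window",
    "angle_histogram",
]

#: resultant lengths below this leave the mean direction undefined
RESULTANT_EPS = 1e-9


@dataclass
class AngleSeries:
    """A dihedral angle sampled over time for one replica, in degrees."""

    time: np.ndarray
    angles: np.ndarray
    angle_name: str = ""
    replica_id: str = ""

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.angles = wrap_angle(np.asarray(self.angles, dtype=float))
        if len(self.time) != len(self.angles):
            raise ValidationError("AngleSeries time/angle length mismatch")

    def __len__(self) -> int:
        return len(self.time)


def wrap_angle(deg):
    """Wrap degrees onto [-180, 180); 180 maps to -180.

    Accepts scalars or arrays; non-finite input is rejected.
    """
    arr = np.asarray(deg, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValidationError("wrap_angle requires finite input")
    wrapped = np.mod(arr + 180.0, 360.0) - 180.0
    if np.isscalar(deg) or arr.ndim == 0:
        return float(wrapped)
    return wrapped


def circular_mean(angles: Sequence[float]) -> tuple[float, float]:
    """Mean direction and resultant length of angles in degrees.

    Returns ``(mean_deg, R)`` with ``mean_deg`` in [-180, 180).  When
    R < 1e-9 the direction is undefined: the mean comes back NaN and a
    RuntimeWarning is emitted.
    """
    a = np.radians(np.asarray(angles, dtype=float).ravel())
    if len(a) == 0:
        raise ValidationError("circular_mean requires at least one angle")
    s = np.mean(np.sin(a))
    c = np.mean(np.cos(a))
    r = math.hypot(s, c)
    if r < RESULTANT_EPS:
        warnings.warn(
            "circular mean undefined: resultant length ~ 0 "
            "(angles cancel, e.g. {0°, 180°})",
            RuntimeWarning,
            stacklevel=2,
        )
        return float("nan"), r
    return wrap_angle(math.degrees(math.atan2(s, c))), r


def circular_mean_trace(replicas: Sequence[AngleSeries]) -> AngleSeries:
    """Per-timepoint circular mean across replicas on a common grid.

    A single replica passes through unchanged.  Timepoints whose
    resultant length vanishes come back NaN (with one warning each).
    """
    if not replicas:
        raise ValidationError("circular_mean_trace requires >= 1 replica")
    ref = replicas[0]
    for s in replicas[1:]:
        if len(s) != len(ref) or not np.array_equal(s.time, ref.time):
            raise ValidationError(
                "replica time grids differ; align before averaging"
            )
    if len(replicas) == 1:
        return ref
    stacked = np.radians(np.vstack([s.angles for s in replicas]))
    s_bar = np.mean(np.sin(stacked), axis=0)
    c_bar = np.mean(np.cos(stacked), axis=0)
    r = np.hypot(s_bar, c_bar)
    mean = wrap_angle(np.degrees(np.arctan2(s_bar, c_bar)))
    undefined = r < RESULTANT_EPS
    if np.any(undefined):
        warnings.warn(
            f"circular mean undefined at {int(undefined.sum())} timepoint(s) "
            "(zero resultant); reported as NaN",
            RuntimeWarning,
            stacklevel=2,
        )
        mean = np.where(undefined, np.nan, mean)
    out = AngleSeries.__new__(AngleSeries)
    out.time = ref.time
    out.angles = mean  # bypass __post_init__: NaNs are intentional here
    out.angle_name = ref.angle_name
    out.replica_id = "circular-mean"
    return out


def concat_replicas(
    series: Sequence[tuple[AngleSeries, AngleSeries]],
) -> tuple[np.ndarray, np.ndarray]:
    """Pool (φ, ψ) observations across replicas of one group.

    Concatenation, not averaging: the pooled cloud represents the whole
    conformational space sampled by the group.  Output length is the sum
    of replica lengths.
    """
    if not series:
        raise ValidationError("concat_replicas requires >= 1 replica pair")
    phis, psis = [], []
    for phi, psi in series:
        if len(phi) != len(psi):
            raise ValidationError(
                f"φ/ψ length mismatch within replica "
                f"{phi.replica_id!r}: {len(phi)} vs {len(psi)}"
            )
        phis.append(phi.angles)
        psis.append(psi.angles)
    return np.concatenate(phis), np.concatenate(psis)


def time_window(s: AngleSeries, t0: float, t1: float) -> AngleSeries:
    """Restrict a series to the closed time interval [t0, t1]."""
    if t0 > t1:
        raise ValidationError(f"empty window: t0={t0} > t1={t1}")
    mask = (s.time >= t0) & (s.time <= t1)
    if not np.any(mask):
        warnings.warn(
            f"time window [{t0}, {t1}] contains no samples", stacklevel=2
        )
    out = AngleSeries.__new__(AngleSeries)
    out.time = s.time[mask]
    out.angles = s.angles[mask]
    out.angle_name = s.angle_name
    out.replica_id = s.replica_id
    return out


def angle_histogram(
    angles: Sequence[float], n_bins: int
) -> tuple[np.ndarray, np.ndarray]:
    """Equal-width histogram over [-180, 180); counts sum to n.

    Returns ``(edges, counts)`` with ``len(edges) == n_bins + 1``.
    """
    if n_bins < 1:
        raise ValidationError("n_bins must be >= 1")
    a = wrap_angle(np.asarray(angles, dtype=float).ravel())
    edges = np.linspace(-180.0, 180.0, n_bins + 1)
    counts, _ = np.histogram(a, bins=edges)
    return edges, counts
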