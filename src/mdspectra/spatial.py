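"""Spatial analyses: ligand occupancy maps, distance-matrix heatmaps,
PCA projection scatter data.

The occupancy map pools ligand atom positions from all frames,
discards z (projection onto the box XY plane) and bins (x, y) on a
regular grid spanning the box dimensions — not the data range — so the
axes are physical box coordinates in nm.  Counts are normalised by
their maximum, giving a relative density in [0, 1].

PCA is consumed, not computed: the projection comes pre-made from
``gmx anaeig -2d`` and only needs column bookkeeping here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import EmptyInputError, ValidationError
from .gromacs_io import XvgTable

__all__ = ["OccupancyMap", "PcaProjection", "occupancy_map", "distance_matrix_sidecar", "pca_scatter"]


@dataclass
class OccupancyMap:
    """Relative 2D ligand density over the simulation box XY plane."""

    x_edges: np.ndarray
    y_edges: np.ndarray
    density: np.ndarray  # (n_bins_y, n_bins_x), max-normalised to 1
    counts: np.ndarray  # raw counts, same shape
    n_samples: int


@dataclass
class PcaProjection:
    """First two principal components per frame, in input order."""

    pc1: np.ndarray
    pc2: np.ndarray
    frame_order: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.pc1) == len(self.pc2) == len(self.frame_order)):
            raise ValidationError("PcaProjection vectors must share one length")


def occupancy_map(
    coords: np.ndarray,
    box_xy: tuple[float, float],
    n_bins: tuple[int, int] = (100, 100),
) -> OccupancyMap:
    """Bin pooled ligand positions onto the box XY plane.

    ``coords`` is (n, 3) or (n, 2) in nm, all frames pooled.  Positions
    outside [0, Lx] x [0, Ly] are wrapped modulo the box length (with a
    warning): periodic images belong inside the box.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.size == 0:
        raise EmptyInputError("occupancy_map received no coordinates")
    if coords.ndim != 2 or coords.shape[1] not in (2, 3):
        raise ValidationError("coords must be (n, 2) or (n, 3)")
    lx, ly = (float(v) for v in box_xy)
    if lx <= 0 or ly <= 0:
        raise ValidationError("box dimensions must be positive")
    nx, ny = n_bins
    if nx < 1 or ny < 1:
        raise ValidationError("n_bins must be >= 1 in each direction")

    xy = coords[:, :2]
    out_of_box = (xy[:, 0] < 0) | (xy[:, 0] > lx) | (xy[:, 1] < 0) | (xy[:, 1] > ly)
    if np.any(out_of_box):
        warnings.warn(
            f"{int(out_of_box.sum())} position(s) outside the box; "
            "wrapping modulo box length",
            stacklevel=2,
        )
        xy = np.column_stack([np.mod(xy[:, 0], lx), np.mod(xy[:, 1], ly)])

    counts, x_edges, y_edges = np.histogram2d(
        xy[:, 0], xy[:, 1], bins=[nx, ny], range=[[0.0, lx], [0.0, ly]]
    )
    counts = counts.T  # histogram2d returns (nx, ny); we keep (ny, nx)
    peak = counts.max()
    density = counts / peak if peak > 0 else counts
    return OccupancyMap(
        x_edges=x_edges,
        y_edges=y_edges,
        density=density,
        counts=counts,
        n_samples=len(xy),
    )


def distance_matrix_sidecar(m: np.ndarray, path: str | Path) -> Path:
    """Write a square distance matrix (nm) as the heatmap's CSV sidecar.

    The sidecar holds exactly the plotted matrix so numeric checks never
    need the figure.
    """
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValidationError(f"distance matrix must be square, got {m.shape}")
    path = Path(path)
    np.savetxt(path, m, delimiter=",", fmt="%.12g")
    return path


def pca_scatter(table: XvgTable) -> PcaProjection:
    """Adopt PC1/PC2 columns from a ``gmx anaeig -2d`` projection table.

    Two-column tables are taken as (PC1, PC2); tables of three or more
    columns are taken as time-prefixed and columns 2–3 are used.
    Frame order follows input order.
    """
    if table.n_cols < 2:
        raise ValidationError(
            f"projection table needs >= 2 columns, got {table.n_cols}"
        )
    if table.n_cols == 2:
        pc1, pc2 = table.columns[0], table.columns[1]
    else:
        pc1, pc2 = table.columns[1], table.columns[2]
    return PcaProjection(
        pc1=np.asarray(pc1, dtype=float),
        pc2=np.asarray(pc2, dtype=float),
        frame_order=np.arange(len(pc1)),
    )
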