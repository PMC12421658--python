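"""Gaussian kernel density estimation, 1D and 2D product-kernel.

The 1D estimator is the textbook Gaussian KDE

    f_hat(x) = 1/(n h sqrt(2 pi)) * sum_i exp(-(x - x_i)^2 / (2 h^2))

with Silverman's rule-of-thumb bandwidth by default,
h = 0.9 * min(sd, IQR/1.349) * n^(-1/5).  The 2D form is the product
kernel with per-axis bandwidths.  Both are evaluated vectorised on a
regular grid; the kernels are deliberately non-periodic — angular data
is pre-wrapped by the ``angular`` module, with an optional ±360°
augmentation flag for edge correction on dihedral plots.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .errors import EmptyInputError, ValidationError

__all__ = ["DensityEstimate", "Density2D", "kde_1d", "kde_2d", "silverman_bandwidth"]

log = logging.getLogger(__name__)

_SQRT_2PI = np.sqrt(2.0 * np.pi)


@dataclass
class DensityEstimate:
    """A 1D density evaluated on a grid."""

    grid: np.ndarray
    density: np.ndarray
    bandwidth: float
    n_obs: int

    def integral(self) -> float:
        """Trapezoidal integral over the evaluation grid."""
        return float(np.trapezoid(self.density, self.grid))


@dataclass
class Density2D:
    """A 2D density on the tensor grid ``y_grid`` x ``x_grid``.

    ``density[i, j]`` is the estimate at ``(x_grid[j], y_grid[i])``.
    """

    x_grid: np.ndarray
    y_grid: np.ndarray
    density: np.ndarray
    bandwidths: tuple[float, float]
    n_obs: int


def silverman_bandwidth(obs: np.ndarray) -> float:
    """Silverman's rule of thumb: 0.9 * min(sd, IQR/1.349) * n^(-1/5).

    Returns 0 for degenerate (constant) samples; callers treat that as
    "no usable bandwidth".
    """
    obs = np.asarray(obs, dtype=float)
    n = len(obs)
    if n < 2:
        return 0.0
    sd = float(np.std(obs, ddof=1))
    q75, q25 = np.percentile(obs, [75, 25])
    iqr = float(q75 - q25)
    scale = min(sd, iqr / 1.349) if iqr > 0 else sd
    return 0.9 * scale * n ** (-0.2)


def _resolve_bandwidth(obs: np.ndarray, h: float | None) -> float:
    if h is not None:
        if h <= 0:
            raise ValidationError(f"bandwidth must be positive, got {h}")
        return float(h)
    auto = silverman_bandwidth(obs)
    if auto <= 0:
        warnings.warn(
            "all observations identical and no bandwidth given; using h = 1",
            stacklevel=3,
        )
        log.warning("degenerate sample: falling back to bandwidth h = 1")
        return 1.0
    return auto


def kde_1d(
    obs: np.ndarray,
    h: float | None = None,
    grid: np.ndarray | None = None,
    n_grid: int = 512,
) -> DensityEstimate:
    """Gaussian KDE of ``obs`` on ``grid``.

    Default grid: ``n_grid`` evenly spaced points spanning
    [min(obs) - 4h, max(obs) + 4h], wide enough that the density
    integrates to ~1.
    """
    obs = np.asarray(obs, dtype=float).ravel()
    n = len(obs)
    if n == 0:
        raise EmptyInputError("kde_1d received no observations")
    h = _resolve_bandwidth(obs, h)
    if grid is None:
        grid = np.linspace(obs.min() - 4 * h, obs.max() + 4 * h, n_grid)
    else:
        grid = np.asarray(grid, dtype=float).ravel()
    # (n_grid, n) pairwise differences; fine at the sizes these plots use
    z = (grid[:, None] - obs[None, :]) / h
    density = np.exp(-0.5 * z * z).sum(axis=1) / (n * h * _SQRT_2PI)
    return DensityEstimate(grid=grid, density=density, bandwidth=h, n_obs=n)


def kde_2d(
    xs: np.ndarray,
    ys: np.ndarray,
    bandwidths: tuple[float, float] | None = None,
    grids: tuple[np.ndarray, np.ndarray] | None = None,
    n_grid: int = 128,
    augment_period: float | None = None,
) -> Density2D:
    """Product-Gaussian KDE of the paired sample ``(xs, ys)``.

    f_hat(x, y) = 1/(n h_x h_y 2 pi)
                  * sum_i exp(-(x-x_i)^2/(2 h_x^2) - (y-y_i)^2/(2 h_y^2))

    ``augment_period`` (e.g. 360 for dihedral degrees) duplicates the
    sample at ±period on both axes before evaluation, a cheap edge
    correction for periodic data; the kernel itself stays non-periodic
    and the normalisation keeps the original n so density mass near the
    window edges is preserved.
    """
    xs = np.asarray(xs, dtype=float).ravel()
    ys = np.asarray(ys, dtype=float).ravel()
    if len(xs) != len(ys):
        raise ValidationError(f"paired sample length mismatch: {len(xs)} vs {len(ys)}")
    n = len(xs)
    if n == 0:
        raise EmptyInputError("kde_2d received no observations")

    if bandwidths is None:
        hx = _resolve_bandwidth(xs, None)
        hy = _resolve_bandwidth(ys, None)
    else:
        hx, hy = (float(b) for b in bandwidths)
        if hx <= 0 or hy <= 0:
            raise ValidationError(f"bandwidths must be positive, got {bandwidths}")

    if grids is None:
        gx = np.linspace(xs.min() - 4 * hx, xs.max() + 4 * hx, n_grid)
        gy = np.linspace(ys.min() - 4 * hy, ys.max() + 4 * hy, n_grid)
    else:
        gx = np.asarray(grids[0], dtype=float).ravel()
        gy = np.asarray(grids[1], dtype=float).ravel()

    ex, ey = xs, ys
    if augment_period is not None:
        p = float(augment_period)
        shifts = [(0.0, 0.0), (-p, 0.0), (p, 0.0), (0.0, -p), (0.0, p)]
        ex = np.concatenate([xs + dx for dx, _ in shifts])
        ey = np.concatenate([ys + dy for _, dy in shifts])

    zx = (gx[:, None] - ex[None, :]) / hx  # (nx, n_eval)
    zy = (gy[:, None] - ey[None, :]) / hy  # (ny, n_eval)
    kx = np.exp(-0.5 * zx * zx)
    ky = np.exp(-0.5 * zy * zy)
    density = (ky @ kx.T) / (n * hx * hy * 2.0 * np.pi)  # (ny, nx)
    return Density2D(
        x_grid=gx, y_grid=gy, density=density, bandwidths=(hx, hy), n_obs=n
    )
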