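"""Synthetic GROMACS-dialect data with known ground truth.

Every generator writes files in the exact dialects ``gromacs_io``
parses (.xvg with grace headers, .xpm with legend lines, plain .dat)
and returns a truth record holding the generating parameters — trend,
noise SD, class counts, circular mean — so tests can check recovery
against known answers without downloading data or running simulations.

Each fixture draws from its own pseudo-random stream derived from
``(seed, kind, replica)``, so replica files are independently
reproducible: regenerating replica 3 alone yields the same bytes as
generating all five.

Default study conditions mirror typical small-peptide MD post-processing:
50 ns trajectories sampled every 10 ps (5001 frames), 3 replicas per
group, ~40-residue peptides.  The generators emulate the statistical
shape of GROMACS output (trends + Gaussian noise, categorical DSSP
grids, von Mises dihedrals), not its physics.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import ValidationError
from .gromacs_io import XpmMatrix, write_xpm, write_xvg, XvgTable

__all__ = [
    "stream",
    "gen_timeseries",
    "gen_dssp_xpm",
    "gen_dihedral",
    "gen_phipsi",
    "gen_distance_xpm",
    "gen_coords",
    "gen_pca2d",
    "generate_tree",
]

DSSP_CODES = ("H", "E", "~", "T", "S", "G")  # one code per canonical class
DSSP_LABELS = {
    "H": "A-Helix",
    "E": "B-Sheet",
    "~": "Coil",
    "T": "Turn",
    "S": "Bend",
    "G": "3-Helix",
}


def stream(seed: int, kind: str, replica: int = 0) -> np.random.Generator:
    """Independent PRNG stream for one fixture, derived from (seed, kind, replica)."""
    tag = zlib.crc32(f"{kind}:{replica}".encode()) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([int(seed), tag]))


@dataclass
class TimeseriesTruth:
    """Generating parameters of one synthetic time series."""

    time_ps: np.ndarray
    trend: np.ndarray
    noise_sd: float
    property_name: str


def gen_timeseries(
    path: str | Path,
    seed: int = 0,
    replica: int = 0,
    n_frames: int = 5001,
    dt_ps: float = 10.0,
    baseline: float = 1.0,
    drift: float = 0.0,
    noise_sd: float = 0.1,
    property_name: str = "RMSD",
    ylabel: str = "RMSD (nm)",
    time_unit: str = "ps",
    with_legend: bool = True,
) -> TimeseriesTruth:
    """Write a trend-plus-Gaussian-noise .xvg time series.

    values[k] = baseline + drift * t_ns[k] + N(0, noise_sd).  The header
    style (ps vs ns label, legend present or not) is configurable so the
    parser sees dialect variety.
    """
    if n_frames < 1 or dt_ps <= 0 or noise_sd < 0:
        raise ValidationError("invalid timeseries spec")
    rng = stream(seed, f"timeseries:{property_name}", replica)
    t_ps = np.arange(n_frames) * dt_ps
    trend = baseline + drift * (t_ps / 1000.0)
    values = trend + rng.normal(0.0, noise_sd, size=n_frames)
    axis = t_ps if time_unit == "ps" else t_ps / 1000.0
    table = XvgTable(
        columns=[axis, values],
        title=property_name,
        xaxis_label=f"Time ({time_unit})",
        yaxis_label=ylabel,
        legends=[property_name] if with_legend else [],
    )
    write_xvg(table, path)
    return TimeseriesTruth(
        time_ps=t_ps, trend=trend, noise_sd=noise_sd, property_name=property_name
    )


@dataclass
class DsspTruth:
    """Exact per-frame class counts of a synthetic DSSP grid."""

    counts: np.ndarray  # (n_frames, 6) in DSSP_CODES order
    codes: tuple[str, ...]
    class_probs: np.ndarray
    n_residues: int


def gen_dssp_xpm(
    path: str | Path,
    seed: int = 0,
    replica: int = 0,
    n_frames: int = 100,
    n_residues: int = 40,
    class_probs: Sequence[float] = (0.35, 0.2, 0.25, 0.1, 0.06, 0.04),
) -> DsspTruth:
    """Write a do_dssp-style .xpm with categorically drawn assignments.

    ``class_probs`` orders as DSSP_CODES (H, E, ~, T, S, G) and must sum
    to 1.  The truth record stores the exact per-frame counts.  Grid
    orientation follows GROMACS: residues on y, frames on x.
    """
    p = np.asarray(class_probs, dtype=float)
    if len(p) != len(DSSP_CODES):
        raise ValidationError(f"need {len(DSSP_CODES)} class probabilities")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValidationError(f"class probabilities sum to {p.sum()}, not 1")
    rng = stream(seed, "dssp_xpm", replica)
    draws = rng.choice(len(DSSP_CODES), size=(n_frames, n_residues), p=p)
    counts = np.stack(
        [(draws == k).sum(axis=1) for k in range(len(DSSP_CODES))], axis=1
    )
    # residues on y, frames on x
    grid = [
        [DSSP_CODES[draws[f, r]] for f in range(n_frames)]
        for r in range(n_residues)
    ]
    legend = {c: (DSSP_LABELS[c], None) for c in DSSP_CODES}
    m = XpmMatrix(
        ncols=n_frames,
        nrows=n_residues,
        chars_per_pixel=1,
        legend=legend,
        codes=grid,
        title="Secondary structure",
        x_ticks=np.arange(n_frames, dtype=float),
        y_ticks=np.arange(n_residues, dtype=float),
    )
    write_xpm(m, path)
    return DsspTruth(
        counts=counts, codes=DSSP_CODES, class_probs=p, n_residues=n_residues
    )


@dataclass
class DihedralTruth:
    """True circular mean (degrees) and concentration of a dihedral fixture."""

    mu_deg: float
    kappa: float


def gen_dihedral(
    path: str | Path,
    seed: int = 0,
    replica: int = 0,
    n_frames: int = 5001,
    dt_ps: float = 10.0,
    mu_deg: float = 60.0,
    kappa: float = 4.0,
    angle_name: str = "dihedral",
) -> DihedralTruth:
    """Write a gmx-angle-style .xvg of von Mises draws around ``mu_deg``."""
    if kappa <= 0:
        raise ValidationError(f"kappa must be positive, got {kappa}")
    rng = stream(seed, f"dihedral:{angle_name}", replica)
    draws = np.degrees(rng.vonmises(np.radians(mu_deg), kappa, size=n_frames))
    draws = np.mod(draws + 180.0, 360.0) - 180.0
    t_ps = np.arange(n_frames) * dt_ps
    table = XvgTable(
        columns=[t_ps, draws],
        title=angle_name,
        xaxis_label="Time (ps)",
        yaxis_label="Angle (degrees)",
        legends=[angle_name],
    )
    write_xvg(table, path)
    return DihedralTruth(mu_deg=float(np.mod(mu_deg + 180, 360) - 180), kappa=kappa)


@dataclass
class PhiPsiTruth:
    mu_phi: float
    mu_psi: float
    kappa: float
    n_pairs: int


def gen_phipsi(
    path: str | Path,
    seed: int = 0,
    replica: int = 0,
    n_pairs: int = 2000,
    mu_phi: float = -63.0,
    mu_psi: float = -43.0,
    kappa: float = 8.0,
) -> PhiPsiTruth:
    """Write a gmx-rama-style .xvg of (φ, ψ) pairs clustered near a basin.

    Defaults sit in the alpha-helical region of the Ramachandran map.
    """
    rng = stream(seed, "phipsi", replica)
    phi = np.degrees(rng.vonmises(np.radians(mu_phi), kappa, size=n_pairs))
    psi = np.degrees(rng.vonmises(np.radians(mu_psi), kappa, size=n_pairs))
    phi = np.mod(phi + 180.0, 360.0) - 180.0
    psi = np.mod(psi + 180.0, 360.0) - 180.0
    table = XvgTable(
        columns=[phi, psi],
        title="Ramachandran",
        xaxis_label="Phi",
        yaxis_label="Psi",
    )
    write_xvg(table, path)
    return PhiPsiTruth(mu_phi=mu_phi, mu_psi=mu_psi, kappa=kappa, n_pairs=n_pairs)


@dataclass
class DistanceXpmTruth:
    """True per-cell matrix values and legend level midpoints."""

    matrix_nm: np.ndarray
    levels: np.ndarray


def gen_distance_xpm(
    path: str | Path,
    seed: int = 0,
    n_residues: int = 30,
    n_levels: int = 8,
    max_nm: float = 2.0,
    chars_per_pixel: int = 1,
) -> DistanceXpmTruth:
    """Write an mdmat-style distance .xpm with known level midpoints.

    Cells are drawn uniformly over the legend's bins; the truth matrix
    holds the bin midpoints, which ``xpm_to_value_matrix`` must recover
    exactly.  A zero diagonal (first bin) is enforced, as mdmat would.
    """
    if n_levels < 2 or n_levels > 60:
        raise ValidationError("n_levels must be in [2, 60]")
    rng = stream(seed, "distance_xpm")
    alphabet = "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789"
    if chars_per_pixel == 1:
        codes = [alphabet[k] for k in range(n_levels)]
    else:
        codes = [
            (alphabet[k] * chars_per_pixel)[:chars_per_pixel] for k in range(n_levels)
        ]
    edges = np.linspace(0.0, max_nm, n_levels + 1)
    mids = 0.5 * (edges[:-1] + edges[1:])
    legend = {
        codes[k]: (f"{edges[k]:.3f}-{edges[k + 1]:.3f}", (edges[k], edges[k + 1]))
        for k in range(n_levels)
    }
    level_idx = rng.integers(0, n_levels, size=(n_residues, n_residues))
    level_idx = np.minimum(level_idx, level_idx.T)  # symmetric, like real distances
    np.fill_diagonal(level_idx, 0)
    grid = [[codes[level_idx[i, j]] for j in range(n_residues)] for i in range(n_residues)]
    m = XpmMatrix(
        ncols=n_residues,
        nrows=n_residues,
        chars_per_pixel=chars_per_pixel,
        legend=legend,
        codes=grid,
        title="Mean Smallest Distance",
        x_ticks=np.arange(1, n_residues + 1, dtype=float),
        y_ticks=np.arange(1, n_residues + 1, dtype=float),
    )
    write_xpm(m, path)
    return DistanceXpmTruth(matrix_nm=mids[level_idx], levels=mids)


@dataclass
class CoordsTruth:
    hotspots: np.ndarray  # (k, 2) centres in nm
    weights: np.ndarray
    box_xy: tuple[float, float]
    n_samples: int


def gen_coords(
    path: str | Path,
    seed: int = 0,
    replica: int = 0,
    n_samples: int = 5000,
    box_xy: tuple[float, float] = (5.14, 5.14),
    hotspots: Sequence[tuple[float, float]] = ((1.5, 1.5), (3.8, 3.2)),
    weights: Sequence[float] | None = None,
    spread_nm: float = 0.25,
    z_nm: float = 2.5,
) -> CoordsTruth:
    """Write a 3-column .dat of ligand positions clustered at hotspots.

    Positions are Gaussian clouds around the hotspot centres, clipped by
    wrapping into the box.  The default box edge matches a typical
    small-peptide cubic box.
    """
    rng = stream(seed, "coords", replica)
    centres = np.asarray(hotspots, dtype=float)
    w = (
        np.full(len(centres), 1.0 / len(centres))
        if weights is None
        else np.asarray(weights, dtype=float) / np.sum(weights)
    )
    which = rng.choice(len(centres), size=n_samples, p=w)
    xy = centres[which] + rng.normal(0.0, spread_nm, size=(n_samples, 2))
    xy[:, 0] = np.mod(xy[:, 0], box_xy[0])
    xy[:, 1] = np.mod(xy[:, 1], box_xy[1])
    z = np.full(n_samples, z_nm) + rng.normal(0.0, spread_nm, size=n_samples)
    data = np.column_stack([xy, z])
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# ligand position x y z (nm)\n")
        for row in data:
            fh.write("  ".join(f"{v:.17g}" for v in row) + "\n")
    return CoordsTruth(
        hotspots=centres, weights=w, box_xy=box_xy, n_samples=n_samples
    )


@dataclass
class Pca2dTruth:
    pc1: np.ndarray
    pc2: np.ndarray


def gen_pca2d(
    path: str | Path,
    seed: int = 0,
    replica: int = 0,
    n_frames: int = 1000,
    scale: tuple[float, float] = (2.0, 1.0),
    with_time: bool = False,
) -> Pca2dTruth:
    """Write an anaeig-style 2D projection .xvg (a drifting point cloud)."""
    rng = stream(seed, "pca2d", replica)
    drift = np.linspace(-1.0, 1.0, n_frames)
    pc1 = scale[0] * drift + rng.normal(0.0, 0.3, size=n_frames)
    pc2 = scale[1] * np.sin(np.pi * drift) + rng.normal(0.0, 0.3, size=n_frames)
    cols = [pc1, pc2]
    if with_time:
        cols = [np.arange(n_frames, dtype=float) * 10.0] + cols
    table = XvgTable(
        columns=cols,
        title="2D projection",
        xaxis_label="projection on eigenvector 1 (nm)",
        yaxis_label="projection on eigenvector 2 (nm)",
    )
    write_xvg(table, path)
    return Pca2dTruth(pc1=pc1, pc2=pc2)


def generate_tree(
    out_dir: str | Path,
    seed: int = 0,
    n_groups: int = 2,
    n_replicas: int = 3,
    n_frames: int = 501,
) -> dict[str, dict]:
    """Emit a full example-data directory tree for every analysis kind.

    Layout: ``<out>/<group>/<kind>/replica<k>.<ext>`` — one folder per
    simulation group, one per analysis, one file per replica.  Returns
    the truth records keyed by relative path.
    """
    out_dir = Path(out_dir)
    truths: dict[str, dict] = {}
    properties = [
        ("rmsd", "RMSD", "RMSD (nm)", 0.8, 0.1),
        ("gyrate", "Radius of gyration", "Rg (nm)", 1.1, 0.05),
        ("sasa", "SASA", "Area (nm\\S2\\N)", 55.0, 2.0),
        ("hbond", "Hydrogen bonds", "Number", 12.0, 2.0),
        ("temperature", "Temperature", "T (K)", 300.0, 2.5),
        ("pressure", "Pressure", "P (bar)", 1.0, 80.0),
        ("density", "Density", "Density (kg/m\\S3\\N)", 1010.0, 3.0),
        ("mindist", "Minimum distance", "Distance (nm)", 0.35, 0.05),
        ("contacts", "Contacts", "Number", 30.0, 4.0),
    ]
    for g in range(n_groups):
        group = f"simulation{g + 1}"
        gseed = seed + 1000 * g
        for kind, name, ylabel, base, sd in properties:
            d = out_dir / group / kind
            d.mkdir(parents=True, exist_ok=True)
            for k in range(n_replicas):
                p = d / f"replica{k + 1}.xvg"
                truth = gen_timeseries(
                    p,
                    seed=gseed,
                    replica=k,
                    n_frames=n_frames,
                    baseline=base + 0.05 * base * g,
                    noise_sd=sd,
                    property_name=name,
                    ylabel=ylabel,
                )
                truths[str(p.relative_to(out_dir))] = {"kind": kind, "truth": truth}
        d = out_dir / group / "dssp"
        d.mkdir(parents=True, exist_ok=True)
        for k in range(n_replicas):
            p = d / f"replica{k + 1}.xpm"
            truth = gen_dssp_xpm(p, seed=gseed, replica=k, n_frames=min(n_frames, 200))
            truths[str(p.relative_to(out_dir))] = {"kind": "dssp", "truth": truth}
        for kind, gen in (
            ("dihedral", gen_dihedral),
            ("phipsi", gen_phipsi),
            ("pca", gen_pca2d),
        ):
            d = out_dir / group / kind
            d.mkdir(parents=True, exist_ok=True)
            for k in range(n_replicas):
                p = d / f"replica{k + 1}.xvg"
                if kind == "dihedral":
                    truth = gen_dihedral(p, seed=gseed, replica=k, n_frames=n_frames)
                elif kind == "phipsi":
                    truth = gen_phipsi(p, seed=gseed, replica=k)
                else:
                    truth = gen_pca2d(p, seed=gseed, replica=k)
                truths[str(p.relative_to(out_dir))] = {"kind": kind, "truth": truth}
        d = out_dir / group / "distmat"
        d.mkdir(parents=True, exist_ok=True)
        p = d / "mdmat.xpm"
        truths[str(p.relative_to(out_dir))] = {
            "kind": "distmat",
            "truth": gen_distance_xpm(p, seed=gseed),
        }
        d = out_dir / group / "coords"
        d.mkdir(parents=True, exist_ok=True)
        for k in range(n_replicas):
            p = d / f"replica{k + 1}.dat"
            truth = gen_coords(p, seed=gseed, replica=k, n_samples=2000)
            truths[str(p.relative_to(out_dir))] = {"kind": "coords", "truth": truth}
    return truths
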