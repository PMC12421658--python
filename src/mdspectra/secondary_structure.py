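"""DSSP secondary-structure probabilities and fractions per frame.

A ``do_dssp`` .xpm grid assigns each residue in each frame one DSSP
code.  Codes are folded into six canonical classes — alpha-helix,
beta-sheet, coil/loop, turn, bend, 3-helix — which partition the
residues, so per-frame percentages sum to 100 and fractions to 1:

    P(i, s) = N(i, s) / N_total * 100      (per-frame probability, %)
    F(i, s) = N(i, s) / N_total            (per-frame fraction)

where N(i, s) counts residues adopting class s in frame i and N_total
is the residue count.  Frames may be pooled across replicas of one
group before boxplotting; fractions are exported per frame as .xlsx
plus a CSV twin.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import MdSpectraError, ValidationError
from .gromacs_io import XpmMatrix

__all__ = [
    "CLASSES",
    "DEFAULT_DSSP_MAPPING",
    "SsAssignments",
    "BoxplotStats",
    "classify_dssp",
    "probability_per_frame",
    "fraction_per_frame",
    "boxplot_summary",
    "export_fraction_table",
]

CLASSES = ("alpha-helix", "beta-sheet", "coil/loop", "turn", "bend", "3-helix")

# B (isolated beta-bridge) folds into beta-sheet, I (pi-helix) into
# coil/loop: the six-class scheme has no slot for either and the
# partition must stay exhaustive.  User-overridable.
DEFAULT_DSSP_MAPPING: dict[str, str] = {
    "H": "alpha-helix",
    "G": "3-helix",
    "E": "beta-sheet",
    "B": "beta-sheet",
    "T": "turn",
    "S": "bend",
    "C": "coil/loop",
    "~": "coil/loop",
    " ": "coil/loop",
    "": "coil/loop",
    "I": "coil/loop",
}


class ClassificationError(MdSpectraError):
    """A grid code has no entry in the DSSP class mapping."""


@dataclass
class SsAssignments:
    """Frame-major grid of secondary-structure classes.

    ``classes[i][r]`` is the class of residue ``r`` in frame ``i``.
    """

    classes: np.ndarray  # (n_frames, n_residues) of class-label strings
    frame_times: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.classes = np.asarray(self.classes, dtype=object)
        if self.classes.ndim != 2:
            raise ValidationError("class grid must be 2-D (frames x residues)")
        if self.classes.shape[1] < 1:
            raise ValidationError("need at least one residue")
        bad = set(self.classes.ravel()) - set(CLASSES)
        if bad:
            raise ValidationError(f"non-canonical classes present: {sorted(bad)}")

    @property
    def n_frames(self) -> int:
        return self.classes.shape[0]

    @property
    def n_residues(self) -> int:
        return self.classes.shape[1]


def classify_dssp(
    m: XpmMatrix,
    mapping: Mapping[str, str] | None = None,
    frames_on_x: bool | None = None,
) -> SsAssignments:
    """Map a DSSP .xpm grid onto the six canonical classes.

    GROMACS ``do_dssp`` puts residues on y and frames on x; when the
    .xpm carries axis ticks, the longer tick array is taken as the
    frame axis, otherwise frames-on-x is assumed.  Pass ``frames_on_x``
    to override auto-detection.
    """
    mapping = dict(DEFAULT_DSSP_MAPPING if mapping is None else mapping)

    unmapped = sorted(
        {c.strip() or c for row in m.codes for c in row if (c.strip() or c) not in mapping and c not in mapping}
    )
    if unmapped:
        raise ClassificationError(
            f"unmapped DSSP codes {unmapped}; known codes: {sorted(mapping)}"
        )

    grid = np.empty((m.nrows, m.ncols), dtype=object)
    for i, row in enumerate(m.codes):
        for j, code in enumerate(row):
            key = code if code in mapping else code.strip()
            grid[i, j] = mapping[key]

    if frames_on_x is None:
        if m.x_ticks is not None and m.y_ticks is not None:
            frames_on_x = len(m.x_ticks) >= len(m.y_ticks)
        else:
            frames_on_x = True
    # frames-on-x means rows are residues: transpose to frame-major
    classes = grid.T if frames_on_x else grid

    times = None
    if frames_on_x and m.x_ticks is not None and len(m.x_ticks) == classes.shape[0]:
        times = np.asarray(m.x_ticks, dtype=float)
    elif not frames_on_x and m.y_ticks is not None and len(m.y_ticks) == classes.shape[0]:
        times = np.asarray(m.y_ticks, dtype=float)

    return SsAssignments(classes=classes, frame_times=times)


def _counts(a: SsAssignments) -> pd.DataFrame:
    """Per-frame residue counts for each canonical class."""
    data = {
        s: (a.classes == s).sum(axis=1).astype(float) for s in CLASSES
    }
    return pd.DataFrame(data)


def probability_per_frame(a: SsAssignments) -> pd.DataFrame:
    """P(i, s) = N(i, s) / N_total * 100, one column per class (%) ."""
    return _counts(a) / a.n_residues * 100.0


def fraction_per_frame(a: SsAssignments) -> pd.DataFrame:
    """F(i, s) = N(i, s) / N_total, one column per class."""
    return _counts(a) / a.n_residues


@dataclass
class BoxplotStats:
    """Five-number summary with Tukey whiskers for one class."""

    median: float
    q1: float
    q3: float
    whisker_lo: float
    whisker_hi: float
    outliers: np.ndarray


def boxplot_summary(p: pd.DataFrame | np.ndarray) -> dict[str, BoxplotStats]:
    """Tukey boxplot statistics per class over pooled frames.

    Quartiles use linear interpolation; whiskers sit at the most
    extreme data inside Q1 - 1.5*IQR and Q3 + 1.5*IQR, with points
    beyond reported as outliers.
    """
    if isinstance(p, np.ndarray):
        p = pd.DataFrame({"values": p})
    out: dict[str, BoxplotStats] = {}
    for col in p.columns:
        v = np.asarray(p[col], dtype=float)
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        iqr = q3 - q1
        lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        inside = v[(v >= lo_fence) & (v <= hi_fence)]
        out[str(col)] = BoxplotStats(
            median=float(med),
            q1=float(q1),
            q3=float(q3),
            whisker_lo=float(inside.min()),
            whisker_hi=float(inside.max()),
            outliers=np.sort(v[(v < lo_fence) | (v > hi_fence)]),
        )
    return out


def export_fraction_table(
    profiles: Mapping[str, pd.DataFrame],
    path: str | Path,
    frame_times: Sequence[float] | None = None,
) -> tuple[Path, Path]:
    """Write per-frame fractions for each group to .xlsx plus a CSV twin.

    One row per frame; the first column is the frame index (or time,
    when given); then one column per class per group, labelled
    ``<group>: <class>``.  All six class columns are always present.
    Returns the (xlsx, csv) paths.
    """
    path = Path(path)
    xlsx_path = path.with_suffix(".xlsx")
    csv_path = path.with_suffix(".csv")

    frames: list[pd.DataFrame] = []
    for group, df in profiles.items():
        block = df.reindex(columns=list(CLASSES)).fillna(0.0)
        block = block.rename(columns={s: f"{group}: {s}" for s in CLASSES})
        frames.append(block.reset_index(drop=True))
    table = pd.concat(frames, axis=1)
    if frame_times is not None:
        table.insert(0, "time", np.asarray(frame_times, dtype=float))
    else:
        table.insert(0, "frame", np.arange(len(table)))

    table.to_excel(xlsx_path, index=False)
    table.to_csv(csv_path, index=False, float_format="%.12g")
    return xlsx_path, csv_path
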