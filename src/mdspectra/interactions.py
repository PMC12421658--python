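"""Protein–ligand interaction traces: contacts, hydrophobic subsets,
minimum distances.

All three analyses consume GROMACS ``gmx mindist``/``gmx hbond`` style
.xvg time series — counts or distances per frame per replica — and
report them as replica-averaged :class:`~mdspectra.replica_stats.SummaryTrace`
objects.  The hydrophobic variant restricts to a user-specified residue
set: with no topology available, residue resolution comes from one
contact-count file per residue per replica, summed over the selection
before averaging across replicas.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .errors import SelectionError, ValidationError
from .gromacs_io import TimeSeries
from .replica_stats import ReplicaSet, SummaryTrace, summarize

__all__ = [
    "ResidueSelection",
    "contacts_summary",
    "hydrophobic_contacts",
    "min_distance_summary",
]

log = logging.getLogger(__name__)

#: mean minimum distance above which frames are flagged as potential
#: dissociation events (advisory, log-only)
DEFAULT_DISSOCIATION_NM = 0.6


@dataclass(frozen=True)
class ResidueSelection:
    """Residue identifiers like "LEU34" chosen by the user as hydrophobic."""

    residues: tuple[str, ...]

    def __init__(self, residues: Sequence[str]):
        res = tuple(residues)
        if not res:
            raise ValidationError("residue selection must be non-empty")
        if len(set(res)) != len(res):
            raise ValidationError("residue selection contains duplicates")
        object.__setattr__(self, "residues", res)

    def __iter__(self):
        return iter(self.residues)

    def __len__(self) -> int:
        return len(self.residues)


def _check_non_negative(groups: Sequence[ReplicaSet], what: str) -> None:
    for rs in groups:
        for s in rs.series:
            if np.any(s.values < 0):
                raise ValidationError(
                    f"negative {what} in group {rs.group_label!r}, "
                    f"replica {s.replica_id!r}"
                )


def contacts_summary(groups: Sequence[ReplicaSet]) -> list[SummaryTrace]:
    """Mean ± SD atomic contact counts per group over time."""
    _check_non_negative(groups, "contact count")
    return [summarize(rs) for rs in groups]


def hydrophobic_contacts(
    per_residue: Mapping[str, ReplicaSet],
    selection: ResidueSelection,
) -> SummaryTrace:
    """Contacts between the ligand and the selected hydrophobic residues.

    Per replica, the per-residue contact counts are summed across the
    selection at every timepoint; the summed traces are then averaged
    across replicas.
    """
    missing = [r for r in selection if r not in per_residue]
    if missing:
        raise SelectionError(
            f"selected residues absent from data: {missing}; "
            f"available: {sorted(per_residue)}"
        )
    picked = [per_residue[r] for r in selection]
    _check_non_negative(picked, "contact count")

    n_rep = picked[0].n_replicas
    for rs in picked:
        if rs.n_replicas != n_rep:
            raise ValidationError(
                "all residues must provide the same number of replicas"
            )

    summed: list[TimeSeries] = []
    for k in range(n_rep):
        ref = picked[0].series[k]
        total = np.zeros_like(ref.values)
        for rs in picked:
            s = rs.series[k]
            if len(s) != len(ref) or not np.array_equal(s.time, ref.time):
                raise ValidationError(
                    f"residue {rs.group_label!r} replica {k} is on a "
                    "different time grid; align inputs first"
                )
            total = total + s.values
        summed.append(
            TimeSeries(
                time=ref.time,
                values=total,
                property_name="hydrophobic contacts",
                replica_id=ref.replica_id,
                time_unit=ref.time_unit,
            )
        )
    label = "+".join(selection)
    return summarize(ReplicaSet(group_label=label, series=summed))


def min_distance_summary(
    groups: Sequence[ReplicaSet],
    dissociation_nm: float = DEFAULT_DISSOCIATION_NM,
) -> list[SummaryTrace]:
    """Mean ± SD ligand–protein minimum distance (nm) per group.

    Frames whose mean distance exceeds ``dissociation_nm`` are flagged
    in the run log as potential dissociation events; the flag is
    advisory and never alters the data.
    """
    _check_non_negative(groups, "distance")
    out = []
    for rs in groups:
        trace = summarize(rs)
        flagged = np.flatnonzero(trace.mean > dissociation_nm)
        if flagged.size:
            log.warning(
                "group %r: mean min-distance exceeds %.2f nm at %d frame(s) "
                "(first at axis value %g) — potential dissociation",
                rs.group_label,
                dissociation_nm,
                flagged.size,
                trace.axis[flagged[0]],
            )
        out.append(trace)
    return out
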