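"""Readers and writers for the GROMACS text formats mdspectra consumes.

Three dialects are supported, and nothing else:

``.xvg``
    Whitespace-delimited numeric columns preceded by ``#`` comment lines
    and ``@`` xmgrace plot directives.  Only the directives the analyses
    need (``title``, ``xaxis label``, ``yaxis label``, ``s<N> legend``)
    are interpreted; every other ``@`` line is carried verbatim so a
    round trip preserves the file.

``.xpm``
    The GROMACS flavour of XPixMap: a C-style char array holding a
    ``ncols nrows ncolors chars_per_pixel`` header, one legend line per
    color (whose comment field carries the value or label), and one
    quoted string per pixel row.  Used for DSSP secondary-structure
    grids and ``gmx mdmat`` inter-residue distance matrices.

``.dat``
    A bare whitespace-delimited numeric table with optional ``#``
    comments (the CPPTRAJ-compatible case).

Raw trajectories (.xtc/.trr) and topologies (.tpr/.gro) are out of
scope by design: those are processed upstream by GROMACS itself.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import UnitError, ValidationError, XpmParseError, XvgParseError

__all__ = [
    "XvgTable",
    "XpmMatrix",
    "TimeSeries",
    "read_xvg",
    "write_xvg",
    "read_dat",
    "read_xpm",
    "write_xpm",
    "xpm_to_value_matrix",
]

_LEGEND_RE = re.compile(r'^s(\d+)\s+legend\s+"(.*)"\s*$')
_TITLE_RE = re.compile(r'^title\s+"(.*)"\s*$')
_XAXIS_RE = re.compile(r'^xaxis\s+label\s+"(.*)"\s*$')
_YAXIS_RE = re.compile(r'^yaxis\s+label\s+"(.*)"\s*$')


@dataclass
class XvgTable:
    """Numeric columns plus the grace metadata of one .xvg file."""

    columns: list[np.ndarray]
    title: str = ""
    xaxis_label: str = ""
    yaxis_label: str = ""
    legends: list[str] = field(default_factory=list)
    extra_directives: list[str] = field(default_factory=list)
    source_path: str = ""

    def __post_init__(self) -> None:
        self.columns = [np.asarray(c, dtype=float) for c in self.columns]
        if not self.columns:
            raise ValidationError("XvgTable requires at least one column")
        n = len(self.columns[0])
        if n < 1:
            raise ValidationError("XvgTable columns must be non-empty")
        if any(len(c) != n for c in self.columns):
            raise ValidationError("XvgTable columns must share one length")

    @property
    def n_rows(self) -> int:
        return len(self.columns[0])

    @property
    def n_cols(self) -> int:
        return len(self.columns)

    def time_unit(self, default: str = "ps") -> str:
        """Infer the x-axis time unit from the axis label.

        GROMACS writes picoseconds unless told otherwise, so ``default``
        is "ps" when the label carries no explicit "(ns)"/"(ps)" tag.
        """
        label = self.xaxis_label.lower()
        if "(ns)" in label:
            return "ns"
        if "(ps)" in label:
            return "ps"
        return default

    def to_timeseries(
        self,
        value_col: int = 1,
        property_name: str | None = None,
        replica_id: str = "",
        unit: str | None = None,
    ) -> "TimeSeries":
        """Promote (column 0, column ``value_col``) to a TimeSeries."""
        if value_col >= self.n_cols:
            raise ValidationError(
                f"column {value_col} requested but table has {self.n_cols} columns"
            )
        return TimeSeries(
            time=self.columns[0],
            values=self.columns[value_col],
            property_name=property_name if property_name is not None else self.title,
            replica_id=replica_id or self.source_path,
            time_unit=unit if unit is not None else self.time_unit(),
        )


@dataclass
class TimeSeries:
    """One property sampled along simulation time for one replica."""

    time: np.ndarray
    values: np.ndarray
    property_name: str = ""
    replica_id: str = ""
    time_unit: str = "ps"

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.time.ndim != 1 or self.values.ndim != 1:
            raise ValidationError("TimeSeries axes must be 1-D")
        if len(self.time) != len(self.values):
            raise ValidationError("TimeSeries time/values length mismatch")
        if len(self.time) < 1:
            raise ValidationError("TimeSeries must hold at least one sample")
        if len(self.time) > 1 and not np.all(np.diff(self.time) > 0):
            raise ValidationError(
                f"TimeSeries time axis must be strictly increasing "
                f"(replica {self.replica_id!r})"
            )

    def __len__(self) -> int:
        return len(self.time)


@dataclass
class XpmMatrix:
    """Parsed GROMACS XPixMap: code grid plus legend.

    ``legend`` maps each pixel code to ``(label, value)`` where ``value``
    is a float (single-number legend), a ``(lo, hi)`` tuple (range
    legend such as mdmat distance bins) or ``None`` (categorical legend
    such as DSSP letters).
    """

    ncols: int
    nrows: int
    chars_per_pixel: int
    legend: dict[str, tuple[str, object]]
    codes: list[list[str]]
    title: str = ""
    x_ticks: np.ndarray | None = None
    y_ticks: np.ndarray | None = None
    source_path: str = ""

    def __post_init__(self) -> None:
        if self.ncols < 1 or self.nrows < 1 or self.chars_per_pixel < 1:
            raise ValidationError("XpmMatrix dimensions must be positive")
        if len(self.codes) != self.nrows:
            raise XpmParseError(
                f"grid has {len(self.codes)} rows, header declares {self.nrows}"
            )
        for i, row in enumerate(self.codes):
            if len(row) != self.ncols:
                raise XpmParseError(
                    f"grid row {i} has {len(row)} cells, header declares {self.ncols}"
                )
            for code in row:
                if len(code) != self.chars_per_pixel:
                    raise XpmParseError(
                        f"code {code!r} in row {i} is not {self.chars_per_pixel} chars"
                    )
                if code not in self.legend:
                    raise XpmParseError(
                        f"code {code!r} in row {i} missing from legend"
                    )


def _parse_float(token: str, path: str, lineno: int) -> float:
    # GROMACS emits both fixed and exponent notation; Fortran D-exponents
    # appear in some third-party .dat files.
    try:
        return float(token)
    except ValueError:
        try:
            return float(token.replace("D", "E").replace("d", "e"))
        except ValueError:
            raise XvgParseError(
                f"{path}: non-numeric token {token!r} on line {lineno}"
            ) from None


def _read_table(path: str | Path, parse_grace: bool) -> XvgTable:
    path = Path(path)
    title = ""
    xaxis = ""
    yaxis = ""
    legends: dict[int, str] = {}
    extra: list[str] = []
    rows: list[list[float]] = []
    width: int | None = None

    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("@"):
                if not parse_grace:
                    continue
                body = line[1:].strip()
                if m := _TITLE_RE.match(body):
                    title = m.group(1)
                elif m := _XAXIS_RE.match(body):
                    xaxis = m.group(1)
                elif m := _YAXIS_RE.match(body):
                    yaxis = m.group(1)
                elif m := _LEGEND_RE.match(body):
                    legends[int(m.group(1))] = m.group(2)
                else:
                    extra.append(body)
                continue
            tokens = line.split()
            values = [_parse_float(t, str(path), lineno) for t in tokens]
            if width is None:
                width = len(values)
            elif len(values) != width:
                raise XvgParseError(
                    f"{path}: ragged row on line {lineno} "
                    f"({len(values)} fields, expected {width})"
                )
            rows.append(values)

    if not rows:
        raise XvgParseError(f"{path}: no data rows found")

    data = np.asarray(rows, dtype=float)
    legend_list = [legends[k] for k in sorted(legends)] if legends else []
    return XvgTable(
        columns=[data[:, j] for j in range(data.shape[1])],
        title=title,
        xaxis_label=xaxis,
        yaxis_label=yaxis,
        legends=legend_list,
        extra_directives=extra,
        source_path=str(path),
    )


def read_xvg(path: str | Path) -> XvgTable:
    """Read a grace-annotated GROMACS .xvg file.

    ``#`` comment lines are skipped; ``@`` directives are parsed into
    metadata; data rows are split on whitespace into float columns.
    Ragged rows and non-numeric tokens raise :class:`XvgParseError`
    with the offending line number.
    """
    return _read_table(path, parse_grace=True)


def read_dat(path: str | Path) -> XvgTable:
    """Read a plain whitespace-delimited .dat table (CPPTRAJ-compatible).

    Same column contract as :func:`read_xvg`, with empty grace metadata.
    ``@`` lines, if present, are ignored rather than interpreted.
    """
    return _read_table(path, parse_grace=False)


def write_xvg(table: XvgTable, path: str | Path) -> None:
    """Write ``table`` in the grace dialect so :func:`read_xvg` re-reads it.

    Numeric values are emitted with 17 significant digits, enough to
    round-trip IEEE doubles exactly.
    """
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# written by mdspectra\n")
        if table.title:
            fh.write(f'@    title "{table.title}"\n')
        if table.xaxis_label:
            fh.write(f'@    xaxis  label "{table.xaxis_label}"\n')
        if table.yaxis_label:
            fh.write(f'@    yaxis  label "{table.yaxis_label}"\n')
        for i, leg in enumerate(table.legends):
            fh.write(f'@ s{i} legend "{leg}"\n')
        for directive in table.extra_directives:
            fh.write(f"@ {directive}\n")
        for i in range(table.n_rows):
            fh.write(
                "  ".join(f"{col[i]:.17g}" for col in table.columns) + "\n"
            )


# --- XPM ---------------------------------------------------------------

_XPM_STRING_RE = re.compile(r'"([^"]*)"')
_RANGE_SEPS = ("--", "–", "-")  # mdmat writes "lo-hi"; keep en-dash tolerant


def _legend_value(label: str) -> object:
    """Interpret a legend comment as a number, a numeric range, or a label."""
    text = label.strip()
    try:
        return float(text)
    except ValueError:
        pass
    for sep in _RANGE_SEPS:
        if sep in text[1:]:  # skip a leading minus sign
            head, _, tail = text[1:].partition(sep)
            try:
                lo = float(text[0] + head)
                hi = float(tail)
                return (lo, hi)
            except ValueError:
                continue
    return None


def read_xpm(path: str | Path) -> XpmMatrix:
    """Read a GROMACS-style .xpm matrix.

    The header string declares ``ncols nrows ncolors chars_per_pixel``;
    the next ``ncolors`` strings define the legend (one code each, with
    the value or class label in the trailing C comment); the remaining
    strings are pixel rows, one per matrix row.  GROMACS also embeds
    ``/* x-axis: ... */`` and ``/* y-axis: ... */`` comment blocks with
    tick values, captured when present.
    """
    path = Path(path)
    title = ""
    x_ticks: list[float] = []
    y_ticks: list[float] = []
    strings: list[str] = []

    with open(path, "r", encoding="utf-8") as fh:
        for raw in fh:
            line = raw.strip()
            if line.startswith("/*"):
                comment = line.strip("/* ").rstrip("*/ ").strip()
                if comment.startswith("title:"):
                    title = comment.partition(":")[2].strip().strip('"')
                elif comment.startswith("x-axis:"):
                    x_ticks.extend(
                        float(t) for t in comment.partition(":")[2].split()
                    )
                elif comment.startswith("y-axis:"):
                    y_ticks.extend(
                        float(t) for t in comment.partition(":")[2].split()
                    )
                continue
            if m := _XPM_STRING_RE.search(line):
                strings.append((m.group(1), line))

    if not strings:
        raise XpmParseError(f"{path}: no xpm strings found")

    header = strings[0][0].split()
    if len(header) != 4:
        raise XpmParseError(f"{path}: malformed xpm header {strings[0][0]!r}")
    ncols, nrows, ncolors, cpp = (int(t) for t in header)
    if len(strings) < 1 + ncolors + nrows:
        raise XpmParseError(
            f"{path}: expected {1 + ncolors + nrows} strings, found {len(strings)}"
        )

    legend: dict[str, tuple[str, object]] = {}
    for text, line in strings[1 : 1 + ncolors]:
        code = text[:cpp]
        # value/label lives in the trailing /* ... */ comment
        cm = re.search(r"/\*\s*(.*?)\s*\*/", line)
        label = cm.group(1).strip().strip('"') if cm else ""
        legend[code] = (label, _legend_value(label))

    codes: list[list[str]] = []
    for rowidx, (text, _) in enumerate(strings[1 + ncolors : 1 + ncolors + nrows]):
        if len(text) != ncols * cpp:
            raise XpmParseError(
                f"{path}: pixel row {rowidx} has {len(text)} chars, "
                f"expected {ncols * cpp}"
            )
        row = [text[j * cpp : (j + 1) * cpp] for j in range(ncols)]
        for code in row:
            if code not in legend:
                raise XpmParseError(
                    f"{path}: code {code!r} in row {rowidx} missing from legend"
                )
        codes.append(row)

    return XpmMatrix(
        ncols=ncols,
        nrows=nrows,
        chars_per_pixel=cpp,
        legend=legend,
        codes=codes,
        title=title,
        x_ticks=np.asarray(x_ticks) if x_ticks else None,
        y_ticks=np.asarray(y_ticks) if y_ticks else None,
        source_path=str(path),
    )


def write_xpm(m: XpmMatrix, path: str | Path) -> None:
    """Write an XpmMatrix in the GROMACS dialect (fixture support)."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("/* XPM */\n")
        if m.title:
            fh.write(f'/* title: "{m.title}" */\n')
        if m.x_ticks is not None:
            fh.write("/* x-axis: " + " ".join(f"{t:g}" for t in m.x_ticks) + " */\n")
        if m.y_ticks is not None:
            fh.write("/* y-axis: " + " ".join(f"{t:g}" for t in m.y_ticks) + " */\n")
        fh.write("static char *mdspectra[] = {\n")
        fh.write(f'"{m.ncols} {m.nrows} {len(m.legend)} {m.chars_per_pixel}",\n')
        for code, (label, value) in m.legend.items():
            fh.write(f'"{code}  c #FFFFFF " /* "{label}" */,\n')
        for row in m.codes:
            fh.write('"' + "".join(row) + '",\n')
        fh.write("};\n")


def xpm_to_value_matrix(m: XpmMatrix) -> np.ndarray:
    """Map every grid cell to its numeric legend value (nrows x ncols).

    Range legends ("lo-hi", as GROMACS mdmat writes for binned
    distances) map to the range midpoint — the unbiased representative
    of a uniform bin.  Categorical legends (DSSP letters) raise
    ``TypeError`` directing the caller to the secondary-structure path.
    """
    values: dict[str, float] = {}
    for code, (label, value) in m.legend.items():
        if isinstance(value, tuple):
            values[code] = 0.5 * (value[0] + value[1])
        elif isinstance(value, float):
            values[code] = value
        else:
            raise TypeError(
                f"legend entry {code!r} ({label!r}) is not numeric; "
                "for DSSP grids use secondary_structure.classify_dssp"
            )
    out = np.empty((m.nrows, m.ncols), dtype=float)
    for i, row in enumerate(m.codes):
        for j, code in enumerate(row):
            out[i, j] = values[code]
    return out
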