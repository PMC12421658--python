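"""Exception hierarchy shared across the package.

Every error raised on bad user input derives from :class:`MdSpectraError`
so the command-line layer can catch one type and exit with a diagnostic.
"""


class MdSpectraError(Exception):
    """Base class for all errors raised by mdspectra."""


class XvgParseError(MdSpectraError):
    """Malformed .xvg/.dat file (no data rows, ragged rows, bad tokens)."""


class XpmParseError(MdSpectraError):
    """Malformed .xpm file (undeclared codes, dimension mismatches)."""


class AlignmentError(MdSpectraError):
    """Replica time axes cannot be reconciled (no overlap)."""


class UnitError(MdSpectraError):
    """Unknown or unsupported physical unit tag."""


class SelectionError(MdSpectraError):
    """A residue selection names residues absent from the data."""


class ValidationError(MdSpectraError):
    """Input values violate a physical contract (e.g. negative counts)."""


class EmptyInputError(MdSpectraError):
    """An operation received no observations."""
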