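"""Exception hierarchy.

Every error raised by the library derives from :class:`MimorankError` so
callers (and the CLI) can distinguish our diagnostics from genuine bugs.
"""


class MimorankError(Exception):
    """Base class for all mimorank errors."""


class CoordinateError(MimorankError):
    """A protein/codon coordinate falls outside the addressed sequence."""


class AlphabetError(MimorankError):
    """A sequence contains characters outside the expected alphabet."""


class ConsistencyError(MimorankError):
    """A mutation's ``from`` residue does not match the current sequence."""


class ConfigurationError(MimorankError):
    """Invalid option/parameter combination supplied by the caller."""


class WindowError(MimorankError):
    """A sliding window does not fit the sequence."""


class FastaError(MimorankError):
    """Malformed FASTA input."""


class CodonTableError(MimorankError):
    """An amino acid is missing from, or inconsistent with, a codon table."""


class SchemaError(MimorankError):
    """A delimited prediction table is missing a required column."""


class TableRowError(MimorankError):
    """One or more rows of a prediction table could not be parsed."""


class UnitError(MimorankError):
    """Scores with mixed units were combined."""


class MissingDataError(MimorankError):
    """No records available for a requested candidate."""


class BinningError(MimorankError):
    """A raw value falls in no conversion bin and clamping is disabled."""


class CalibrationError(MimorankError):
    """Degenerate range supplied to bin calibration."""


class CompletenessError(MimorankError):
    """A scorecard is missing a converted field needed for a total."""
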