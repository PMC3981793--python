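"""Exception hierarchy for rnathermscan.

All library errors derive from :class:`ThermoScanError` so the CLI can map
any expected failure onto a one-line diagnostic and a nonzero exit code.
"""


class ThermoScanError(Exception):
    """Base class for all rnathermscan errors."""


class SequenceError(ThermoScanError):
    """Invalid or malformed sequence input (bad residues, empty records)."""


class FastaFormatError(SequenceError):
    """A FASTA file could not be parsed into usable records."""


class ParameterError(ThermoScanError):
    """Missing or malformed thermodynamic parameter data."""


class StructureError(ThermoScanError):
    """An invalid secondary structure (unbalanced, crossing, non-canonical)."""


class DotBracketParseError(StructureError):
    """Unbalanced dot-bracket string; carries the position of the violation."""

    def __init__(self, message: str, position: int):
        super().__init__(message)
        self.position = position


class EngineError(ThermoScanError):
    """An external folding engine failed or produced unparseable output."""

    def __init__(self, message: str, raw_output: str | None = None):
        super().__init__(message)
        self.raw_output = raw_output


class ScanError(ThermoScanError):
    """Scan configuration incompatible with the input sequence."""


class GenerationError(ThermoScanError):
    """The synthetic-thermometer generator could not satisfy its constraints."""


class ReliabilityWarning(UserWarning):
    """Scan parameters outside the range where folding is considered reliable."""
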