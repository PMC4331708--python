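"""Exception hierarchy.

Everything raised on bad *data* derives from :class:`DataError` so the CLI can
map it to a distinct exit status; programming errors stay ordinary Python
exceptions.
"""


class MirHairpinError(Exception):
    """Base class for all package-specific errors."""


class DataError(MirHairpinError):
    """Invalid or malformed input data."""


class FastaParseError(DataError):
    """Malformed FASTA input; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class SequenceValidationError(DataError):
    """A sequence contains residues outside the accepted alphabet."""


class StructureParseError(DataError):
    """Malformed dot-bracket string or structure file."""


class SamplingError(DataError):
    """Fragment sampling could not satisfy the requested constraints."""


class BackendUnavailableError(MirHairpinError):
    """The requested external folding backend cannot be loaded."""
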