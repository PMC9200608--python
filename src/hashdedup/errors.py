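"""Exception hierarchy.

All data-level problems derive from :class:`DedupError` so callers (notably
the CLI) can distinguish bad input data (exit code 1) from bad usage
(exit code 2, :class:`ConfigurationError`).
"""

from __future__ import annotations


class DedupError(Exception):
    """Base class for all errors raised by this package."""


class MalformedRecordError(DedupError):
    """A sequence record violates its format contract.

    Carries the 0-based ``ordinal`` of the offending record when known.
    """

    def __init__(self, message: str, ordinal: int | None = None):
        self.ordinal = ordinal
        if ordinal is not None:
            message = f"record {ordinal}: {message}"
        super().__init__(message)


class InvalidCharacterError(MalformedRecordError):
    """A residue outside the declared alphabet was encountered."""

    def __init__(self, character: str, record: str | None = None,
                 ordinal: int | None = None):
        self.character = character
        self.record = record
        where = f" in record {record!r}" if record else ""
        super().__init__(
            f"invalid character {character!r}{where}", ordinal=ordinal)


class UnsupportedOperationError(DedupError):
    """An operation undefined for the current alphabet (e.g. reverse
    complement of a protein sequence)."""


class ConfigurationError(DedupError):
    """Mutually inconsistent run options; raised before any record is read."""


class UnrecognizedFormatError(DedupError):
    """Input is neither FASTQ nor FASTA (or is empty)."""


class FormatMismatchError(DedupError):
    """Records cannot be serialized in the requested format (e.g. FASTQ
    output of records without quality strings)."""


class PairSynchronizationError(DedupError):
    """Paired input files disagree on record count.

    ``surviving`` names the file that still had records; ``ordinal`` is the
    0-based pair position at which the other file ran out.
    """

    def __init__(self, surviving: str, ordinal: int):
        self.surviving = surviving
        self.ordinal = ordinal
        super().__init__(
            f"paired inputs out of sync: {surviving!r} still has records at "
            f"pair ordinal {ordinal} but its mate file is exhausted")


class GenerationError(DedupError):
    """A synthetic-fixture specification cannot be satisfied."""
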