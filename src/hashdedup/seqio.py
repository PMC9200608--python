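"""Streaming FASTQ/FASTA readers and writers, plain or gzip.

Readers are single-pass and hold one record at a time.  FASTQ is the strict
4-line dialect (universal in modern data); FASTA sequences may span multiple
lines.  Both formats round-trip byte-faithfully through
:func:`read_records` / :func:`write_records` (identifier, description,
sequence, quality).  ``"-"`` designates standard input/output.
"""

from __future__ import annotations

import gzip
import io
import sys
import zlib
from dataclasses import dataclass
from typing import IO, Iterable, Iterator

from .errors import FormatMismatchError, MalformedRecordError, \
    PairSynchronizationError, UnrecognizedFormatError

FASTQ = "fastq"
FASTA = "fasta"
PLAIN = "plain"
GZIP = "gzip"

_GZIP_MAGIC = b"\x1f\x8b"

#: Default FASTA output line width.
FASTA_WRAP = 60


@dataclass
class SequenceRecord:
    """One read: identifier (no leading sigil), residues, optional quality.

    ``description`` is the header text after the first whitespace, preserved
    verbatim on output.  ``ordinal`` is the 0-based position in the source
    file.
    """

    identifier: str
    sequence: str
    quality: str | None = None
    description: str | None = None
    ordinal: int = 0

    @property
    def header(self) -> str:
        if self.description:
            return f"{self.identifier} {self.description}"
        return self.identifier


@dataclass
class RecordPair:
    """Mate records sharing one ordinal position in two synchronized files."""

    mate1: SequenceRecord
    mate2: SequenceRecord
    ordinal: int = 0


def detect_format(path: str) -> tuple[str, str]:
    """Sniff ``(format, compression)`` from the first bytes of ``path``.

    Gzip is recognized by its magic bytes; the record format by the first
    non-blank character of the (decompressed) text: ``@`` means FASTQ,
    ``>`` means FASTA.  Anything else, or an empty source, raises
    :class:`UnrecognizedFormatError`.  On standard input the bytes are
    peeked, not consumed, so the stream can still be parsed afterwards.
    """
    if path == "-":
        buffered = sys.stdin.buffer
        buffered.peek(1)  # type: ignore[union-attr]
        head = buffered.peek(io.DEFAULT_BUFFER_SIZE)  # type: ignore
    else:
        with open(path, "rb") as fh:
            head = fh.read(io.DEFAULT_BUFFER_SIZE)
    compression = GZIP if head[:2] == _GZIP_MAGIC else PLAIN
    if compression == GZIP:
        text = zlib.decompressobj(wbits=16 + zlib.MAX_WBITS).decompress(head)
        if not text.strip() and path != "-":
            with gzip.open(path, "rb") as gz:
                text = gz.read(io.DEFAULT_BUFFER_SIZE)
    else:
        text = head
    first = b""
    for byte in text:
        if not chr(byte).isspace():
            first = bytes([byte])
            break
    if first == b"@":
        return FASTQ, compression
    if first == b">":
        return FASTA, compression
    raise UnrecognizedFormatError(
        f"{path!r}: cannot determine sequence format "
        f"(first character {first!r}, expected '@' or '>')")


def _open_binary(path: str) -> IO[bytes]:
    if path == "-":
        return sys.stdin.buffer
    return open(path, "rb")


def _open_text_for_read(path: str, compression: str) -> IO[str]:
    raw = _open_binary(path)
    if compression == GZIP:
        return io.TextIOWrapper(gzip.open(raw), encoding="ascii")
    if isinstance(raw, io.BufferedReader):
        return io.TextIOWrapper(raw, encoding="ascii")
    return io.TextIOWrapper(io.BufferedReader(raw), encoding="ascii")


def _open_text_for_write(path: str, compress: bool) -> IO[str]:
    if path == "-":
        sink: IO[bytes] = sys.stdout.buffer
    else:
        sink = open(path, "wb")
    if compress:
        # fixed mtime and no embedded filename keep output byte-stable
        return io.TextIOWrapper(
            gzip.GzipFile(fileobj=sink, mode="wb", mtime=0, filename=""),
            encoding="ascii")
    return io.TextIOWrapper(sink, encoding="ascii")


def _split_header(line: str) -> tuple[str, str | None]:
    head = line[1:].rstrip("\n")
    if not head:
        return "", None
    parts = head.split(None, 1)
    identifier = parts[0]
    description = parts[1] if len(parts) == 2 else None
    return identifier, description


def read_records(path: str, format: str | None = None,
                 compression: str | None = None) -> Iterator[SequenceRecord]:
    """Stream records from ``path``, auto-detecting format when not given.

    FASTQ records must be exactly four lines; a truncated trailing record,
    a separator line not starting with ``+``, a quality/sequence length
    mismatch, or an empty sequence raise :class:`MalformedRecordError`
    citing the record ordinal.
    """
    if format is None or compression is None:
        det_format, det_compression = detect_format(path)
        format = format or det_format
        compression = compression or det_compression
    stream = _open_text_for_read(path, compression)
    if format == FASTQ:
        return _read_fastq(stream)
    if format == FASTA:
        return _read_fasta(stream)
    raise ValueError(f"unknown format {format!r}")


def _read_fastq(stream: IO[str]) -> Iterator[SequenceRecord]:
    with stream:
        ordinal = 0
        while True:
            header = stream.readline()
            if not header:
                return
            if header.strip() == "":
                continue
            lines = [stream.readline() for _ in range(3)]
            if any(not ln for ln in lines):
                raise MalformedRecordError(
                    "truncated FASTQ record (fewer than 4 lines)",
                    ordinal=ordinal)
            seq_line, sep_line, qual_line = \
                (ln.rstrip("\n") for ln in lines)
            if not header.startswith("@"):
                raise MalformedRecordError(
                    f"FASTQ header must start with '@', got "
                    f"{header.rstrip()!r}", ordinal=ordinal)
            if not sep_line.startswith("+"):
                raise MalformedRecordError(
                    f"FASTQ separator line must start with '+', got "
                    f"{sep_line!r}", ordinal=ordinal)
            if not seq_line:
                raise MalformedRecordError("empty sequence", ordinal=ordinal)
            if len(qual_line) != len(seq_line):
                raise MalformedRecordError(
                    f"quality length {len(qual_line)} != sequence length "
                    f"{len(seq_line)}", ordinal=ordinal)
            identifier, description = _split_header(header)
            yield SequenceRecord(identifier=identifier, sequence=seq_line,
                                 quality=qual_line, description=description,
                                 ordinal=ordinal)
            ordinal += 1


def _read_fasta(stream: IO[str]) -> Iterator[SequenceRecord]:
    with stream:
        ordinal = 0
        header: str | None = None
        chunks: list[str] = []
        for line in stream:
            if line.startswith(">"):
                if header is not None:
                    yield _finish_fasta(header, chunks, ordinal)
                    ordinal += 1
                header = line
                chunks = []
            elif line.strip():
                if header is None:
                    raise MalformedRecordError(
                        "sequence data before first FASTA header", ordinal=0)
                chunks.append(line.strip())
        if header is not None:
            yield _finish_fasta(header, chunks, ordinal)


def _finish_fasta(header: str, chunks: list[str],
                  ordinal: int) -> SequenceRecord:
    sequence = "".join(chunks)
    if not sequence:
        raise MalformedRecordError("empty sequence", ordinal=ordinal)
    identifier, description = _split_header(header)
    return SequenceRecord(identifier=identifier, sequence=sequence,
                          description=description, ordinal=ordinal)


def read_pairs(path1: str, path2: str, format: str | None = None,
               compression: str | None = None) -> Iterator[RecordPair]:
    """Lock-step iteration over two synchronized mate files.

    Raises :class:`PairSynchronizationError` naming the surviving file and
    the pair ordinal if one file runs out before the other.
    """
    stream1 = read_records(path1, format, compression)
    stream2 = read_records(path2, format, compression)
    sentinel = object()
    ordinal = 0
    while True:
        r1 = next(stream1, sentinel)
        r2 = next(stream2, sentinel)
        if r1 is sentinel and r2 is sentinel:
            return
        if r2 is sentinel:
            raise PairSynchronizationError(path1, ordinal)
        if r1 is sentinel:
            raise PairSynchronizationError(path2, ordinal)
        yield RecordPair(r1, r2, ordinal=ordinal)  # type: ignore[arg-type]
        ordinal += 1


def _format_record(rec: SequenceRecord, format: str,
                   wrap: int = FASTA_WRAP) -> str:
    if format == FASTQ:
        if rec.quality is None:
            raise FormatMismatchError(
                f"record {rec.identifier!r} has no quality string; "
                f"cannot write FASTQ")
        return f"@{rec.header}\n{rec.sequence}\n+\n{rec.quality}\n"
    if format == FASTA:
        body = "\n".join(rec.sequence[i:i + wrap]
                         for i in range(0, len(rec.sequence), wrap))
        return f">{rec.header}\n{body}\n"
    raise ValueError(f"unknown format {format!r}")


def write_pairs(path1: str, path2: str, pairs: Iterable[RecordPair],
                format: str, compress: bool = False,
                wrap: int = FASTA_WRAP) -> int:
    """Stream pairs into two synchronized files; returns pairs written.

    Both files receive the surviving pairs in identical order, one record
    at a time (no buffering), preserving mate synchronization.
    """
    count = 0
    out1 = _open_text_for_write(path1, compress)
    out2 = _open_text_for_write(path2, compress)
    try:
        for pair in pairs:
            out1.write(_format_record(pair.mate1, format, wrap))
            out2.write(_format_record(pair.mate2, format, wrap))
            count += 1
    finally:
        out1.close()
        out2.close()
    return count


def write_records(path: str, records: Iterable[SequenceRecord],
                  format: str, compress: bool = False,
                  wrap: int = FASTA_WRAP) -> int:
    """Write ``records`` to ``path`` and return the count written.

    FASTQ output requires every record to carry a quality string of matching
    length; FASTA output wraps sequence lines at ``wrap`` columns and drops
    qualities.
    """
    count = 0
    out = _open_text_for_write(path, compress)
    try:
        for rec in records:
            out.write(_format_record(rec, format, wrap))
            count += 1
    finally:
        if path == "-" and not compress:
            out.flush()
            out.detach()  # leave sys.stdout.buffer open
        else:
            # GzipFile.close flushes the trailer but never closes a
            # caller-supplied fileobj, so stdout survives the gzip case.
            out.close()
    return count
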