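"""Reading, writing and length-normalization of quality-score data (QSD).

A FASTQ record stores per-base quality as ASCII characters with a +33
offset (Phred+33); the usable code range is therefore 0..93.  This module
extracts quality lines from FASTQ or from a plain "one quality string per
line" text file into :class:`QsdBlock`, and converts variable-length
collections to a fixed-length block plus a reversible side-stream of the
original lengths.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, List, Sequence

PHRED_OFFSET = 33
MAX_CODE = 93  # ASCII '~' (126) minus the offset


class QsdFormatError(ValueError):
    """Malformed FASTQ structure or unparseable input."""


class AlphabetError(ValueError):
    """A symbol code or quality character outside the Phred+33 range."""


class CorruptionError(ValueError):
    """Streams that are internally inconsistent (decoder-side damage)."""


@dataclass
class QualityRecord:
    """One quality string as integer codes plus its original position."""

    symbols: List[int]
    index: int

    def __len__(self) -> int:
        return len(self.symbols)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, QualityRecord):
            return NotImplemented
        return self.symbols == other.symbols and self.index == other.index


@dataclass
class QsdBlock:
    """An ordered collection of quality records.

    ``fixed_length`` is true when every record has the same length ``L``
    (vacuously true for the empty block).  ``alphabet_size`` counts the
    distinct codes present.
    """

    records: List[QualityRecord] = field(default_factory=list)

    @property
    def m(self) -> int:
        return len(self.records)

    @property
    def fixed_length(self) -> bool:
        lengths = {len(r) for r in self.records}
        return len(lengths) <= 1

    @property
    def L(self) -> int:
        if not self.records:
            return 0
        lengths = {len(r) for r in self.records}
        if len(lengths) != 1:
            raise ValueError("block is not fixed-length")
        return lengths.pop()

    @property
    def alphabet_size(self) -> int:
        return len({s for r in self.records for s in r.symbols})

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, QsdBlock):
            return NotImplemented
        return self.records == other.records


@dataclass
class LengthStream:
    """Original per-record lengths, in original order."""

    lengths: List[int]


def _record_from_ascii(line: bytes, index: int) -> QualityRecord:
    symbols = []
    for b in line:
        code = b - PHRED_OFFSET
        if not 0 <= code <= MAX_CODE:
            raise AlphabetError(
                f"record {index}: byte {b} outside printable Phred+33 range 33-126"
            )
        symbols.append(code)
    return QualityRecord(symbols=symbols, index=index)


def read_qsd(path, format: str = "lines") -> QsdBlock:
    """Read a :class:`QsdBlock` from ``path``.

    ``format='fastq'`` consumes the quality line of each 4-line FASTQ
    group; ``format='lines'`` treats every LF-terminated line as one
    quality string.
    """
    with open(path, "rb") as fh:
        data = fh.read()
    return parse_qsd(data, format=format)


def parse_qsd(data: bytes, format: str = "lines") -> QsdBlock:
    """Parse raw bytes (see :func:`read_qsd`)."""
    if format not in ("fastq", "lines"):
        raise ValueError(f"unknown format {format!r}")
    records: List[QualityRecord] = []
    if format == "lines":
        if data:
            lines = data.split(b"\n")
            if lines and lines[-1] == b"":
                lines.pop()  # trailing newline
            for i, line in enumerate(lines):
                records.append(_record_from_ascii(line.rstrip(b"\r"), i))
    else:
        lines = data.split(b"\n")
        if lines and lines[-1] == b"":
            lines.pop()
        if len(lines) % 4 != 0:
            raise QsdFormatError(
                f"FASTQ line count {len(lines)} is not a multiple of 4"
            )
        for group in range(len(lines) // 4):
            header, seq, plus, qual = (
                lines[4 * group + j].rstrip(b"\r") for j in range(4)
            )
            if not header.startswith(b"@") or not plus.startswith(b"+"):
                raise QsdFormatError(f"malformed FASTQ group at record {group}")
            if len(qual) != len(seq):
                raise QsdFormatError(
                    f"record {group}: quality length {len(qual)} != "
                    f"sequence length {len(seq)}"
                )
            records.append(_record_from_ascii(qual, group))
    return QsdBlock(records=records)


def serialize_lines(block: QsdBlock) -> bytes:
    """The canonical lines-format byte serialization of a block.

    This is also the byte stream the archive's integrity digest covers.
    """
    buf = io.BytesIO()
    for rec in block.records:
        for code in rec.symbols:
            if not 0 <= code <= MAX_CODE:
                raise AlphabetError(f"symbol code {code} outside [0, {MAX_CODE}]")
            buf.write(bytes((code + PHRED_OFFSET,)))
        buf.write(b"\n")
    return buf.getvalue()


def write_qsd(block: QsdBlock, path, format: str = "lines") -> None:
    """Write a block to ``path`` in ``lines`` or quality-only FASTQ form."""
    if format == "lines":
        payload = serialize_lines(block)
    elif format == "fastq-quality-only":
        buf = io.BytesIO()
        for rec in block.records:
            qual = bytes(c + PHRED_OFFSET for c in rec.symbols)
            for code in rec.symbols:
                if not 0 <= code <= MAX_CODE:
                    raise AlphabetError(
                        f"symbol code {code} outside [0, {MAX_CODE}]"
                    )
            buf.write(b"@%d\n" % rec.index)
            buf.write(b"N" * len(rec.symbols) + b"\n")
            buf.write(b"+\n")
            buf.write(qual + b"\n")
        payload = buf.getvalue()
    else:
        raise ValueError(f"unknown format {format!r}")
    with open(path, "wb") as fh:
        fh.write(payload)


def normalize_lengths(block: QsdBlock) -> tuple[QsdBlock, LengthStream]:
    """Pad every record to the maximum length, recording original lengths.

    Padding repeats the record's final symbol so that it extends an
    existing run (friendly to the downstream run-length levels); empty
    records are padded with code 0.  Exactly inverted by
    :func:`restore_lengths`.
    """
    if block.m < 1:
        raise ValueError("normalize_lengths requires at least one record")
    lengths = [len(r) for r in block.records]
    L = max(lengths)
    fixed_records = []
    for rec in block.records:
        pad_sym = rec.symbols[-1] if rec.symbols else 0
        padded = rec.symbols + [pad_sym] * (L - len(rec.symbols))
        fixed_records.append(QualityRecord(symbols=padded, index=rec.index))
    return QsdBlock(records=fixed_records), LengthStream(lengths=lengths)


def restore_lengths(fixed: QsdBlock, lengths: LengthStream) -> QsdBlock:
    """Truncate padded records back to their original lengths."""
    if len(lengths.lengths) != fixed.m:
        raise CorruptionError(
            f"length stream has {len(lengths.lengths)} entries "
            f"for {fixed.m} records"
        )
    L = fixed.L if fixed.m else 0
    out = []
    for rec, n in zip(fixed.records, lengths.lengths):
        if n > L:
            raise CorruptionError(f"record {rec.index}: stored length {n} > L={L}")
        out.append(QualityRecord(symbols=rec.symbols[:n], index=rec.index))
    return QsdBlock(records=out)
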