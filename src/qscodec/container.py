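"""Bit-exact archive container (magic ``QSC1``).

Layout (all integers little-endian; see FORMAT.md for the byte-level
specification):

* fixed header: magic, version, flags, record count m, fixed length L,
  partitioning parameters k and tau, gate coefficients theta, chunk count;
* a global stream section (partition marks, optional original lengths);
* one section per chunk: record count, level-flag byte, chunk alphabet
  size, then its streams;
* trailer: SHA-256 digest of the original quality-line bytes.

Every stream entry records its codec id, raw element count and payload
size, so decompression needs no side information.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from typing import List, Optional

from .backend import CODEC_IDS, CODEC_NAMES
from .qsd_io import CorruptionError

MAGIC = b"QSC1"
VERSION = 1
FLAG_VARIABLE_LENGTH = 0x01
FIXED_POINT = 10_000

# stream ids
SID_MARKS = 0
SID_LENGTHS = 1
SID_TABLE_ALPHABET = 2
SID_TABLE_PERMS = 3
SID_SYMBOLS = 4
SID_RUN_LENGTHS_BASE = 5  # level l run lengths at id 4 + l (l in 1..3)


class ArchiveFormatError(ValueError):
    """Not an archive, or an unsupported version."""


@dataclass
class StreamEntry:
    stream_id: int
    codec: str  # codec name, see backend.CODEC_IDS
    n: int  # raw element count
    payload: bytes


@dataclass
class ChunkEntry:
    n_records: int
    level_flags: int  # bitfield, bit l = level l enabled
    alphabet_size: int
    streams: List[StreamEntry] = field(default_factory=list)


@dataclass
class Archive:
    m: int
    L: int
    k: int
    tau: float
    theta: tuple
    variable_length: bool
    global_streams: List[StreamEntry]
    chunks: List[ChunkEntry]
    digest: bytes  # SHA-256 of the original quality-line bytes

    @property
    def chunk_count(self) -> int:
        return len(self.chunks)


def _pack_stream(entry: StreamEntry) -> bytes:
    head = struct.pack("<BBQQ", entry.stream_id, CODEC_IDS[entry.codec],
                       entry.n, len(entry.payload))
    return head + entry.payload


class _Reader:
    def __init__(self, data: bytes):
        self.data = data
        self.pos = 0

    def take(self, n: int) -> bytes:
        if self.pos + n > len(self.data):
            raise CorruptionError("archive truncated")
        out = self.data[self.pos : self.pos + n]
        self.pos += n
        return out

    def unpack(self, fmt: str):
        return struct.unpack(fmt, self.take(struct.calcsize(fmt)))


def _read_stream(r: _Reader) -> StreamEntry:
    stream_id, codec_id, n, payload_len = r.unpack("<BBQQ")
    if codec_id not in CODEC_NAMES:
        raise CorruptionError(f"unknown codec id {codec_id}")
    payload = r.take(payload_len)
    return StreamEntry(stream_id=stream_id, codec=CODEC_NAMES[codec_id],
                       n=n, payload=payload)


def write_archive(archive: Archive, path) -> None:
    """Serialize an :class:`Archive` to ``path``."""
    if len(archive.digest) != 32:
        raise ValueError("digest must be 32 bytes (SHA-256)")
    flags = FLAG_VARIABLE_LENGTH if archive.variable_length else 0
    theta_fixed = [round(t * FIXED_POINT) for t in archive.theta]
    if len(theta_fixed) != 4:
        raise ValueError("theta must have 4 coefficients")
    parts = [
        MAGIC,
        struct.pack("<BBQLBH", VERSION, flags, archive.m, archive.L,
                    archive.k, round(archive.tau * FIXED_POINT)),
        struct.pack("<4i", *theta_fixed),
        struct.pack("<H", archive.chunk_count),
        struct.pack("<B", len(archive.global_streams)),
    ]
    for entry in archive.global_streams:
        parts.append(_pack_stream(entry))
    for chunk in archive.chunks:
        parts.append(struct.pack("<QBBB", chunk.n_records, chunk.level_flags,
                                 chunk.alphabet_size, len(chunk.streams)))
        for entry in chunk.streams:
            parts.append(_pack_stream(entry))
    parts.append(archive.digest)
    with open(path, "wb") as fh:
        fh.write(b"".join(parts))


def read_archive(path) -> Archive:
    """Parse and validate an archive; exact inverse of :func:`write_archive`."""
    with open(path, "rb") as fh:
        data = fh.read()
    r = _Reader(data)
    if r.take(4) != MAGIC:
        raise ArchiveFormatError("bad magic: not a QSC1 archive")
    version, flags, m, L, k, tau_fixed = r.unpack("<BBQLBH")
    if version != VERSION:
        raise ArchiveFormatError(f"unsupported archive version {version}")
    theta_fixed = r.unpack("<4i")
    (chunk_count,) = r.unpack("<H")
    (n_global,) = r.unpack("<B")
    global_streams = [_read_stream(r) for _ in range(n_global)]
    chunks = []
    for _ in range(chunk_count):
        n_records, level_flags, alphabet_size, n_streams = r.unpack("<QBBB")
        streams = [_read_stream(r) for _ in range(n_streams)]
        chunks.append(ChunkEntry(n_records=n_records, level_flags=level_flags,
                                 alphabet_size=alphabet_size, streams=streams))
    digest = r.take(32)
    if r.pos != len(data):
        raise CorruptionError(
            f"{len(data) - r.pos} trailing bytes after archive trailer"
        )
    return Archive(m=m, L=L, k=k, tau=tau_fixed / FIXED_POINT,
                   theta=tuple(t / FIXED_POINT for t in theta_fixed),
                   variable_length=bool(flags & FLAG_VARIABLE_LENGTH),
                   global_streams=global_streams, chunks=chunks, digest=digest)
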