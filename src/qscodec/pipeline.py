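"""End-to-end compress / decompress / verify pipeline.

Compression: read -> (length-normalize if variable) -> k-mer partition ->
cyclic chunking per partition -> per-chunk run-length prediction mapping
-> per-stream entropy coding -> archive.  Decompression is the exact
reverse; the archive's SHA-256 digest of the original quality-line bytes
is recomputed and compared after reconstruction.

Chunk boundaries are recorded in the archive, so an archive written with
any worker count decodes identically regardless of the decoder's worker
count.
"""

from __future__ import annotations

import hashlib
import os
from dataclasses import dataclass
from typing import List, Optional, Sequence

from . import container, qsd_io, rlp
from .backend import compress_stream, decompress_stream
from .container import (Archive, ChunkEntry, StreamEntry, SID_LENGTHS,
                        SID_MARKS, SID_RUN_LENGTHS_BASE, SID_SYMBOLS,
                        SID_TABLE_ALPHABET, SID_TABLE_PERMS)
from .partition import (DEFAULT_K, DEFAULT_TAU, PartitionResult, cyclic_divide,
                        cyclic_merge, merge_partitions, partition_sequences)
from .qsd_io import CorruptionError, QsdBlock, QualityRecord
from .rlp import DEFAULT_THETA, ContextTable, MappedStream, apply_prpm, invert_prpm


class IntegrityError(Exception):
    """Digest mismatch between the archive and the reconstructed data."""


@dataclass
class CompressionSummary:
    m: int
    total_chars: int
    compressed_bytes: int

    @property
    def bits_per_base(self) -> Optional[float]:
        if self.total_chars == 0:
            return None
        return 8.0 * self.compressed_bytes / self.total_chars


def _detect_format(path) -> str:
    name = str(path).lower()
    if name.endswith((".fastq", ".fq")):
        return "fastq"
    return "lines"


def _encode_chunk(records: Sequence[QualityRecord], L: int,
                  theta: Sequence[float]) -> ChunkEntry:
    if not records or L == 0:
        return ChunkEntry(n_records=len(records), level_flags=0,
                          alphabet_size=0, streams=[])
    mapped = apply_prpm(records, theta)
    alphabet, perms = mapped.table.to_index_streams()
    A_c = len(alphabet)
    flags_byte = sum(1 << lvl for lvl, on in enumerate(mapped.level_flags) if on)
    perm_codec = "ac1" if A_c > 1 else "store"
    streams = [
        StreamEntry(SID_TABLE_ALPHABET, "store", A_c,
                    compress_stream(alphabet, "store")),
        StreamEntry(SID_TABLE_PERMS, perm_codec, len(perms),
                    compress_stream(perms, perm_codec, alphabet_size=A_c)),
        StreamEntry(SID_SYMBOLS, "ac1", len(mapped.symbols),
                    compress_stream(mapped.symbols, "ac1", alphabet_size=A_c)),
    ]
    for lvl in sorted(mapped.level_lengths):
        lengths = mapped.level_lengths[lvl]
        streams.append(StreamEntry(SID_RUN_LENGTHS_BASE - 1 + lvl, "gp1",
                                   len(lengths),
                                   compress_stream(lengths, "gp1")))
    return ChunkEntry(n_records=len(records), level_flags=flags_byte,
                      alphabet_size=A_c, streams=streams)


def _decode_chunk(chunk: ChunkEntry, L: int) -> List[QualityRecord]:
    if not chunk.streams:
        if chunk.n_records and L:
            raise CorruptionError("chunk with records but no streams")
        return [QualityRecord(symbols=[], index=i)
                for i in range(chunk.n_records)]
    by_id = {s.stream_id: s for s in chunk.streams}
    try:
        alpha_entry = by_id[SID_TABLE_ALPHABET]
        perm_entry = by_id[SID_TABLE_PERMS]
        sym_entry = by_id[SID_SYMBOLS]
    except KeyError as exc:
        raise CorruptionError(f"chunk missing stream id {exc}") from None
    alphabet = decompress_stream(alpha_entry.payload, alpha_entry.codec,
                                 alpha_entry.n)
    A_c = len(alphabet)
    if A_c != chunk.alphabet_size:
        raise CorruptionError("chunk alphabet size mismatch")
    perms = decompress_stream(perm_entry.payload, perm_entry.codec,
                              perm_entry.n, alphabet_size=A_c)
    table = ContextTable.from_index_streams(alphabet, perms)
    symbols = decompress_stream(sym_entry.payload, sym_entry.codec,
                                sym_entry.n, alphabet_size=A_c)
    flags = [bool(chunk.level_flags >> lvl & 1) for lvl in range(rlp.N_LEVELS)]
    level_lengths = {}
    for lvl in range(1, rlp.N_LEVELS):
        if flags[lvl]:
            entry = by_id.get(SID_RUN_LENGTHS_BASE - 1 + lvl)
            if entry is None:
                raise CorruptionError(f"run-length stream for level {lvl} missing")
            level_lengths[lvl] = decompress_stream(entry.payload, entry.codec,
                                                   entry.n)
    mapped = MappedStream(level_flags=flags, symbols=symbols,
                          level_lengths=level_lengths, table=table)
    return invert_prpm(mapped, [L] * chunk.n_records)


def compress(input_path, output_path, workers: int = 1, k: int = DEFAULT_K,
             tau: float = DEFAULT_TAU, theta: Sequence[float] = DEFAULT_THETA,
             input_format: Optional[str] = None) -> CompressionSummary:
    """Compress a QSD file into a ``QSC1`` archive."""
    if workers < 1:
        raise ValueError("workers must be >= 1")
    fmt = input_format or _detect_format(input_path)
    block = qsd_io.read_qsd(input_path, format=fmt)
    raw = qsd_io.serialize_lines(block)
    digest = hashlib.sha256(raw).digest()
    total_chars = sum(len(r) for r in block.records)
    try:
        if block.m == 0:
            archive = Archive(m=0, L=0, k=k, tau=tau, theta=tuple(theta),
                              variable_length=False, global_streams=[],
                              chunks=[], digest=digest)
            container.write_archive(archive, output_path)
            return CompressionSummary(0, 0, os.path.getsize(output_path))

        variable = not block.fixed_length
        if variable:
            fixed, lens = qsd_io.normalize_lengths(block)
        else:
            fixed, lens = block, None
        L = fixed.L
        part = partition_sequences(fixed, k=k, tau=tau)
        chunk_lists = cyclic_divide(part.Q0, workers) + cyclic_divide(
            part.Q1, workers)
        chunks = [_encode_chunk(records, L, theta) for records in chunk_lists]
        global_streams = [
            StreamEntry(SID_MARKS, "ac1", len(part.B),
                        compress_stream(part.B, "ac1", alphabet_size=2)),
        ]
        if variable:
            global_streams.append(
                StreamEntry(SID_LENGTHS, "gp1", len(lens.lengths),
                            compress_stream(lens.lengths, "gp1")))
        archive = Archive(m=block.m, L=L, k=k, tau=tau, theta=tuple(theta),
                          variable_length=variable,
                          global_streams=global_streams, chunks=chunks,
                          digest=digest)
        container.write_archive(archive, output_path)
    except Exception:
        if os.path.exists(output_path):
            os.unlink(output_path)
        raise
    return CompressionSummary(block.m, total_chars,
                              os.path.getsize(output_path))


def decompress(archive_path, output_path, workers: int = 1) -> QsdBlock:
    """Reconstruct the original QSD file from an archive and verify it.

    ``workers`` is accepted for interface symmetry; chunk boundaries come
    from the archive, so the output never depends on it.
    """
    arc = container.read_archive(archive_path)
    if arc.m == 0:
        block = QsdBlock(records=[])
    else:
        marks_entry = next((s for s in arc.global_streams
                            if s.stream_id == SID_MARKS), None)
        if marks_entry is None:
            raise CorruptionError("archive missing partition marks stream")
        B = decompress_stream(marks_entry.payload, marks_entry.codec,
                              marks_entry.n, alphabet_size=2)
        if arc.chunk_count % 2 != 0:
            raise CorruptionError("chunk count must cover two partitions")
        W = arc.chunk_count // 2
        chunk_records = [_decode_chunk(c, arc.L) for c in arc.chunks]
        Q0 = cyclic_merge(chunk_records[:W])
        Q1 = cyclic_merge(chunk_records[W:])
        merged = merge_partitions(
            PartitionResult(Q0=Q0, Q1=Q1, B=B, k=arc.k, tau=arc.tau))
        for i, rec in enumerate(merged.records):
            rec.index = i
        if arc.variable_length:
            len_entry = next((s for s in arc.global_streams
                              if s.stream_id == SID_LENGTHS), None)
            if len_entry is None:
                raise CorruptionError("archive missing lengths stream")
            lens = qsd_io.LengthStream(
                decompress_stream(len_entry.payload, len_entry.codec,
                                  len_entry.n))
            merged = qsd_io.restore_lengths(merged, lens)
        block = merged
    raw = qsd_io.serialize_lines(block)
    if hashlib.sha256(raw).digest() != arc.digest:
        raise IntegrityError(
            "reconstructed data does not match the archive digest")
    with open(output_path, "wb") as fh:
        fh.write(raw)
    return block


def verify(path_a, path_b) -> bool:
    """True iff the two files have identical SHA-256 digests."""
    digests = []
    for path in (path_a, path_b):
        with open(path, "rb") as fh:
            digests.append(hashlib.sha256(fh.read()).digest())
    return digests[0] == digests[1]
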