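# QSC1 archive format

All integers are little-endian. One archive holds one compressed
quality-score collection plus everything needed to restore it bit-exactly.

## Fixed header

| field | type | meaning |
|---|---|---|
| magic | 4 bytes | `QSC1` |
| version | u8 | format version, currently 1 |
| flags | u8 | bit 0: input was variable-length (a LENGTHS stream is present); bits 1-7 reserved, zero |
| m | u64 | record count |
| L | u32 | fixed (post-normalization) record length |
| k | u8 | k-mer length used by the partition statistic |
| tau | u16 | partition threshold, fixed-point ×10⁴ |
| theta | 4 × i32 | run-length gate coefficients, fixed-point ×10⁴ |
| chunk count | u16 | total chunks = 2 × W (W per partition; partition Q0's chunks first) |
| global stream count | u8 | number of global stream entries that follow |

## Stream entry

Every stream (global or chunk-local) is laid out as:

| field | type |
|---|---|
| stream id | u8 |
| codec id | u8 |
| raw element count n | u64 |
| payload byte count | u64 |
| payload | bytes |

Stream ids: 0 MARKS (partition marks B, one 0/1 per record, original
order), 1 LENGTHS (original per-record lengths, only when flags bit 0 is
set), 2 TABLE_ALPHABET (the chunk's sorted distinct symbol codes),
3 TABLE_PERMS (context-table permutations: for the start context then each
alphabet symbol ascending, the candidate ordering as indices into the
alphabet, concatenated — (A+1)·A values), 4 SYMBOLS (the terminal symbol
stream of the mapping cascade), 5/6/7 run-length side-streams of cascade
levels 1/2/3.

Codec ids: 0 `ac0`, 1 `ac1`, 2 `ac2` (adaptive arithmetic coder, order
0/1/2), 3 `store` (raw LEB128), 4 `gp1` (zlib), 5 `gp2` (bz2), 6 `gp3`
(lzma). Non-arithmetic codecs operate on the stream's LEB128
serialization (unsigned, 7 data bits per byte, high bit = continuation).
Arithmetic streams use the chunk's alphabet size (MARKS: alphabet 2;
TABLE_PERMS and SYMBOLS: A of the chunk).

## Chunk section

After the global streams, `chunk count` chunk sections follow, ordered:
partition Q0's W round-robin chunks, then partition Q1's. Each:

| field | type |
|---|---|
| record count | u64 |
| level flags | u8 | bit l set = cascade level l enabled (bit 0 always set for non-empty chunks) |
| alphabet size A | u8 |
| stream count | u8 |
| streams | stream entries |

A chunk with zero records (or with L = 0) carries no streams.

## Trailer

32 bytes: SHA-256 digest of the original quality data in its canonical
lines serialization (each record's Phred+33 ASCII followed by LF).
Decompression recomputes and compares this digest.

## Validation rules

Readers must reject: wrong magic (format error), unknown version or codec
id, truncated payloads, and trailing bytes after the digest (corruption
errors). A digest mismatch after reconstruction is an integrity error.
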