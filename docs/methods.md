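# Methods

## Model and procedure

`qscodec` treats a quality-score collection as `m` symbol sequences over
the Phred+33 code range 0–93 and compresses them in two reversible
stages.

**Length normalization.** Variable-length collections are padded to the
maximum record length `L`; padding repeats each record's final symbol so
it extends an existing run rather than introducing a sentinel, and the
original lengths are kept as an explicit side-stream (zlib-coded LEB128
integers). Empty records are padded with code 0. This makes every later
stage operate on a rectangular block with record boundaries implied by
`L`, at the cost of storing the lengths — an overhead that is why
variable-length (long-read) data compresses slightly worse than its
fixed-length entropy would suggest.

**Partitioning.** The per-record redundancy statistic is
`s = 1 − D/(L−k+1)` with `D` the number of distinct k-mers: 0 for a
record of maximal k-mer diversity, approaching 1 for a constant record,
and defined as 0 when `L < k`. Records with `s ≥ τ` go to partition Q0,
the rest to Q1, and a marks bit-stream B (entropy-coded like any other
stream) records the assignment so the merge is order-exact. The point of
the split is that the two classes have very different statistics; each
partition gets its own context tables and its own chunks, which also
bounds per-task memory. Defaults `k = 4`, `τ = 0.5`: a 4-mer is the
shortest window that separates "runs with occasional steps" from
genuinely diverse strings, and `τ = 0.5` puts the boundary at "half the
windows are repeats". Both are CLI flags, and both are serialized in the
archive header, so decompression never recomputes or guesses them.

**Prediction mapping.** For each chunk, a counting pass builds, for the
start context and every alphabet symbol `c`, the alphabet ordered by
decreasing frequency of "symbol follows `c`" (ties by ascending code).
Each symbol is replaced by its rank in its predecessor's ordering.
Because adjacent quality values are strongly correlated, rank 0
dominates — on a first-order chain with stay-probability `p`, at least
about `p` of all residuals are 0 — and the residual stream has long runs.

**Gated run-length cascade.** Levels 1–3 each replace the current stream
by (run symbol, run length) streams; level `l+1` operates on level `l`'s
run-symbol stream, and length streams are terminal side outputs. A level
fires only when the linear gate `θ·x > 0` with
`x = [1, n_runs/n, n/n_runs, A/94]` approves; the default
`θ = (−2, 0, 1, 0)` reduces to *mean run length > 2*, exactly the
break-even point at which `2·n_runs < n` guarantees the token count
strictly decreases. The cascade stops at the first declined gate. The
coefficients are a config parameter and are stored (fixed-point ×10⁴) in
the archive, so decoding is self-describing even with a custom gate.

**Entropy backend.** A 32-bit range coder (carry-propagating, LZMA-style
renormalization) with adaptive per-context frequency models: counts start
at 1, grow by 32 per coded symbol, and all counts halve (floored at 1)
when a context total exceeds 2¹⁶. Orders 0/1/2 are available; defaults
are order 1 for marks, context-table permutations and symbol streams, and
zlib over LEB128 bytes for the unbounded run-length integers. The
constants (increment 32, rescale 2¹⁶, 32-bit state) are fixed so payloads
are bit-reproducible across platforms. Context tables are shipped in the
archive as explicit permutations — the minimal summary of the counting
pass sufficient to rebuild the decoder's table bit-exactly — rather than
being re-derived from decoded data, which removes any risk of
encoder/decoder asymmetry.

**Container and integrity.** The `QSC1` archive (FORMAT.md) serializes
all parameters, the chunk layout, and per-stream codec ids, and ends with
the SHA-256 of the original quality lines; decompression recomputes the
digest and fails loudly on mismatch. The worker count `W` fixes the
round-robin chunk boundaries recorded in the archive; correctness never
depends on scheduling, so any archive decodes identically under any
decoder worker setting. Chunk processing runs sequentially in-process:
the hot loops are pure Python and GIL-bound, so thread pools buy nothing
and process pools cost more in serialization than they save at the scales
this implementation targets; the format-level chunk contract is what
matters for interoperable parallel implementations.

## Numerical and degenerate-input choices

- Ties in context orderings break by ascending symbol code; ties in the
  gate (`θ·x = 0`) decline the level. Both are deterministic.
- Empty input produces a valid minimal archive that decompresses to an
  empty file; `m = 1`, `L = 1`, `L = 0` (all-empty records) and
  full-94-symbol-alphabet inputs are all exercised by tests.
- The adaptive coder's payload obeys
  `bits ≤ n·log₂A + C·A·log₂(n+A) + 48` with `C = 8` (the 48 covers the
  coder's fixed flush); on iid-uniform input the order-0 payload is
  within ~1.2% of `n·log₂A` at `n = 4096`, and a constant stream of 10⁴
  symbols costs under 0.01 bits/symbol.
- Per-chunk context tables cost `(A+1)·A` permutation entries; for wide
  alphabets (A ≈ 94) this is the dominant overhead on small corpora and
  amortizes with corpus size. This is visible in the adversarial-iid
  numbers from `scripts/acceptance.py`, which are reported at desk-scale
  corpus sizes (10⁵-character corpora, a deliberate scaling-down of the
  multi-gigabyte collections such a tool targets).

## Synthetic data: what it does and does not show

The generator draws each record from a first-order Markov chain: the
first symbol comes from a stationary distribution (shifted by a
positional drift term evaluated at the draw position and clipped to the
alphabet), and each later symbol repeats its predecessor with the stay
probability `p`, otherwise it is redrawn from the stationary law — so
the effective repeat probability is `p + (1−p)·π(prev)`. Bundled
profiles:

| profile | A | p | lengths | notes |
|---|---|---|---|---|
| binned-short | 4 | 0.9 | fixed 100 | binned Illumina-like; uniform stationary, codes 2–5 |
| hiseq-short | 40 | 0.6 | fixed 100 | ramp stationary, drift −0.05/position (3′ degradation) |
| long-read | 64 | 0.4 | 500–20 000 | wide alphabet, weak runs, variable lengths |
| adversarial-iid | 94 | 0.0 | fixed 100 | worst case: full alphabet, no structure |

For the binned-short profile the exact conditional entropy
`H(next | prev)` is 0.50 bits/symbol (closed form, cross-checked against
a plug-in estimate from simulated data in the tests); the full pipeline
reaches ≈ 0.78 bits/base at 10⁵ characters, strictly below the 2.0
bits/base order-0 floor for a 4-symbol alphabet — the gain the
prediction mapping exists to deliver.

The profiles capture run persistence, alphabet width, positional drift
and length variability. They do **not** capture instrument-specific cycle
artefacts, tile/flow-cell structure, or correlation between quality and
base identity — so passing tests demonstrate exact losslessness on *any*
byte stream in range and realistic compression behaviour on
Markov-structured data, but measured ratios on real instrument files will
differ from the synthetic figures.

## Known limitations

- Phred+33 only; offset-64 dialects are out of scope.
- Only the quality stream of a FASTQ file is compressed; headers and
  bases are not (a whole-FASTQ tool would wrap this codec).
- Exactly two partitions, first-order contexts, and a fixed four-level
  cascade; the gate coefficients are configurable but not learned.
- Throughput is that of a pure-Python arithmetic coder — suitable for
  library use, testing and moderate corpora, not for multi-gigabyte
  production archiving.
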