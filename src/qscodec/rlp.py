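"""Run-length prediction mapping (the PRPM stage).

Adjacent quality values are strongly correlated, so a symbol is well
predicted by its predecessor.  The mapping replaces each symbol by the
*rank* of that symbol in a frequency-ordered candidate list conditioned on
the previous symbol (level 0, always applied).  On redundant data the
residual stream is dominated by rank 0 and carries long runs, so up to
three cascaded run-length passes (levels 1-3) each split the current
stream into a run-symbol stream and a run-length stream.  Every
run-length level is gated by a linear score on simple stream statistics,
so the cascade only fires when it strictly shrinks the token count; the
whole mapping is exactly invertible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

from .qsd_io import AlphabetError, CorruptionError, QualityRecord

#: theta . [1, n_runs/n, n/n_runs, A/94] > 0  <=>  mean run length > 2,
#: the break-even point where (symbol, length) pairs beat raw symbols.
DEFAULT_THETA = (-2.0, 0.0, 1.0, 0.0)

N_LEVELS = 4  # level 0 = prediction mapping, levels 1-3 = gated RLE
START = -1  # context of the first position in each record


@dataclass
class ContextTable:
    """Per-context candidate orderings for the prediction mapping.

    For the start context and for every alphabet symbol ``c``, ``orders[c]``
    is the alphabet sorted by decreasing count of "symbol follows c"
    (ties broken by ascending symbol code).
    """

    alphabet: List[int]
    orders: Dict[int, List[int]]  # context (START or symbol) -> permutation

    @property
    def A(self) -> int:
        return len(self.alphabet)

    def rank_maps(self) -> Dict[int, Dict[int, int]]:
        """symbol -> rank lookup per context."""
        return {
            ctx: {sym: r for r, sym in enumerate(order)}
            for ctx, order in self.orders.items()
        }

    def to_index_streams(self) -> tuple[List[int], List[int]]:
        """Serialize as (alphabet codes, concatenated permutation indices).

        Permutations are emitted for the start context then each alphabet
        symbol in ascending order, each as indices into ``alphabet``.
        """
        pos = {sym: i for i, sym in enumerate(self.alphabet)}
        perms: List[int] = []
        for ctx in [START] + self.alphabet:
            perms.extend(pos[sym] for sym in self.orders[ctx])
        return list(self.alphabet), perms

    @classmethod
    def from_index_streams(cls, alphabet: Sequence[int],
                           perms: Sequence[int]) -> "ContextTable":
        A = len(alphabet)
        if len(perms) != (A + 1) * A:
            raise CorruptionError(
                f"context table stream has {len(perms)} entries, "
                f"expected {(A + 1) * A}"
            )
        orders: Dict[int, List[int]] = {}
        contexts = [START] + list(alphabet)
        for i, ctx in enumerate(contexts):
            chunk = perms[i * A : (i + 1) * A]
            if sorted(chunk) != list(range(A)):
                raise CorruptionError(f"context {ctx}: not a permutation")
            orders[ctx] = [alphabet[j] for j in chunk]
        return cls(alphabet=list(alphabet), orders=orders)


@dataclass
class GateFeatures:
    """Stream statistics feeding the run-length gate."""

    n: int
    n_runs: int
    distinct: int

    @property
    def x(self) -> List[float]:
        return [
            1.0,
            self.n_runs / self.n,
            self.n / self.n_runs,
            self.distinct / 94.0,
        ]

    @classmethod
    def from_stream(cls, stream: Sequence[int]) -> "GateFeatures":
        if not stream:
            raise ValueError("gate features require a non-empty stream")
        n_runs = 1 + sum(1 for i in range(1, len(stream))
                         if stream[i] != stream[i - 1])
        return cls(n=len(stream), n_runs=n_runs, distinct=len(set(stream)))


@dataclass
class MappedStream:
    """Output of the full cascade.

    ``symbols`` is the symbol stream at the deepest applied level (equal to
    the raw prediction residuals when no run-length level fired);
    ``level_lengths[l]`` holds the run-length side-stream of each fired
    level l in {1, 2, 3}.  Streams exist exactly for the enabled levels.
    """

    level_flags: List[bool]
    symbols: List[int]
    level_lengths: Dict[int, List[int]]
    table: ContextTable


def build_context_table(records: Sequence[QualityRecord]) -> ContextTable:
    """First pass: count successor frequencies and rank each context."""
    counts: Dict[int, Dict[int, int]] = {}
    present = set()
    for rec in records:
        prev = START
        for sym in rec.symbols:
            counts.setdefault(prev, {})[sym] = counts.get(prev, {}).get(sym, 0) + 1
            present.add(sym)
            prev = sym
    if not present:
        raise ValueError("cannot build a context table from zero symbols")
    alphabet = sorted(present)
    orders: Dict[int, List[int]] = {}
    for ctx in [START] + alphabet:
        ctx_counts = counts.get(ctx, {})
        orders[ctx] = sorted(alphabet,
                             key=lambda s: (-ctx_counts.get(s, 0), s))
    return ContextTable(alphabet=alphabet, orders=orders)


def prediction_map(records: Sequence[QualityRecord],
                   table: ContextTable) -> List[int]:
    """Symbols -> ranks given the previous symbol's candidate ordering."""
    ranks = table.rank_maps()
    out: List[int] = []
    for rec in records:
        prev = START
        for sym in rec.symbols:
            try:
                out.append(ranks[prev][sym])
            except KeyError:
                raise AlphabetError(
                    f"symbol {sym} absent from context table alphabet"
                ) from None
            prev = sym
    return out


def prediction_unmap(residuals: Sequence[int], table: ContextTable,
                     record_lengths: Sequence[int]) -> List[QualityRecord]:
    """Exact inverse of :func:`prediction_map`."""
    if len(residuals) != sum(record_lengths):
        raise CorruptionError(
            f"{len(residuals)} residuals for {sum(record_lengths)} symbols"
        )
    A = table.A
    out: List[QualityRecord] = []
    pos = 0
    for idx, L_r in enumerate(record_lengths):
        prev = START
        symbols: List[int] = []
        for _ in range(L_r):
            rank = residuals[pos]
            pos += 1
            if not 0 <= rank < A:
                raise CorruptionError(f"residual rank {rank} >= alphabet {A}")
            sym = table.orders[prev][rank]
            symbols.append(sym)
            prev = sym
        out.append(QualityRecord(symbols=symbols, index=idx))
    return out


def run_length_pass(stream: Sequence[int]) -> tuple[List[int], List[int]]:
    """Maximal runs -> parallel (symbol, length) streams."""
    symbols: List[int] = []
    lengths: List[int] = []
    for sym in stream:
        if symbols and symbols[-1] == sym:
            lengths[-1] += 1
        else:
            symbols.append(sym)
            lengths.append(1)
    return symbols, lengths


def run_length_unpass(symbols: Sequence[int],
                      lengths: Sequence[int]) -> List[int]:
    """Exact inverse of :func:`run_length_pass`."""
    if len(symbols) != len(lengths):
        raise CorruptionError("run symbol/length stream counts differ")
    out: List[int] = []
    for sym, n in zip(symbols, lengths):
        if n < 1:
            raise CorruptionError(f"run length {n} < 1")
        out.extend([sym] * n)
    return out


def gate_score(features: GateFeatures,
               theta: Sequence[float] = DEFAULT_THETA) -> bool:
    """Linear gate: apply run-length encoding iff theta . x > 0."""
    score = sum(t * xi for t, xi in zip(theta, features.x))
    return score > 0.0


def apply_prpm(records: Sequence[QualityRecord],
               theta: Sequence[float] = DEFAULT_THETA) -> MappedStream:
    """Full cascade: prediction mapping then up to three gated RLE levels.

    Level l+1 operates on level l's run-symbol stream; run-length streams
    are terminal side outputs.  The cascade stops at the first gate that
    declines.
    """
    if not records:
        raise ValueError("apply_prpm requires at least one record")
    table = build_context_table(records)
    current = prediction_map(records, table)
    flags = [True, False, False, False]
    level_lengths: Dict[int, List[int]] = {}
    for level in range(1, N_LEVELS):
        if not current:
            break
        if not gate_score(GateFeatures.from_stream(current), theta):
            break
        symbols, lengths = run_length_pass(current)
        flags[level] = True
        level_lengths[level] = lengths
        current = symbols
    return MappedStream(level_flags=flags, symbols=current,
                        level_lengths=level_lengths, table=table)


def invert_prpm(mapped: MappedStream,
                record_lengths: Sequence[int]) -> List[QualityRecord]:
    """Undo applied levels deepest-first, then the prediction mapping."""
    if not mapped.level_flags or not mapped.level_flags[0]:
        raise CorruptionError("level 0 (prediction mapping) must be enabled")
    applied = [lvl for lvl in range(1, N_LEVELS) if mapped.level_flags[lvl]]
    if sorted(mapped.level_lengths) != applied:
        raise CorruptionError("level flags inconsistent with stored streams")
    current = list(mapped.symbols)
    for level in reversed(applied):
        current = run_length_unpass(current, mapped.level_lengths[level])
    return prediction_unmap(current, mapped.table, record_lengths)
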