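"""Sequence partitioning by k-mer redundancy (the PSPM stage).

Quality strings vary widely in local redundancy: binned short-read data is
dominated by long runs and tiny alphabets, while raw long-read data is
closer to high-entropy text.  Splitting a collection into a high-redundancy
partition Q0 and a remainder Q1 lets each partition be modelled (and
scheduled) separately, at the cost of a one-bit-per-record marks stream B
that makes the split order-exactly reversible.

The redundancy statistic for a record of length L_r at k-mer size k is

    s = 1 - D / (L_r - k + 1)

where D is the number of distinct length-k substrings; s is 0 for a record
of maximal k-mer diversity and approaches 1 for a constant record.  Records
shorter than k score 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence, TypeVar

from .qsd_io import CorruptionError, QsdBlock, QualityRecord

DEFAULT_K = 4
DEFAULT_TAU = 0.5

T = TypeVar("T")


@dataclass
class PartitionResult:
    """Two partitions plus the per-record marks stream B.

    ``B[i]`` is 0 when original record ``i`` went to ``Q0`` (score >= tau)
    and 1 when it went to ``Q1``; within each partition the original order
    is preserved.
    """

    Q0: List[QualityRecord]
    Q1: List[QualityRecord]
    B: List[int]
    k: int
    tau: float


def kmer_statistic(record: QualityRecord, k: int) -> float:
    """Redundancy score in [0, 1]; higher means fewer distinct k-mers."""
    if k < 1:
        raise ValueError("k must be >= 1")
    L_r = len(record.symbols)
    if L_r < k:
        return 0.0
    windows = L_r - k + 1
    distinct = len({tuple(record.symbols[i : i + k]) for i in range(windows)})
    return 1.0 - distinct / windows


def partition_sequences(block: QsdBlock, k: int = DEFAULT_K,
                        tau: float = DEFAULT_TAU) -> PartitionResult:
    """Split a fixed-length block into Q0 (score >= tau) and Q1."""
    if not block.fixed_length:
        raise ValueError("partitioning requires a fixed-length block")
    Q0: List[QualityRecord] = []
    Q1: List[QualityRecord] = []
    B: List[int] = []
    for rec in block.records:
        if kmer_statistic(rec, k) >= tau:
            Q0.append(rec)
            B.append(0)
        else:
            Q1.append(rec)
            B.append(1)
    return PartitionResult(Q0=Q0, Q1=Q1, B=B, k=k, tau=tau)


def merge_partitions(result: PartitionResult) -> QsdBlock:
    """Rebuild the original-order block by consuming Q0/Q1 as B directs."""
    if result.B.count(0) != len(result.Q0) or result.B.count(1) != len(result.Q1):
        raise CorruptionError(
            "marks stream bit counts inconsistent with partition sizes"
        )
    it0 = iter(result.Q0)
    it1 = iter(result.Q1)
    records = [next(it0) if bit == 0 else next(it1) for bit in result.B]
    return QsdBlock(records=records)


def cyclic_divide(items: Sequence[T], W: int) -> List[List[T]]:
    """Round-robin split into W ordered subsequences (item i -> i mod W)."""
    if W < 1:
        raise ValueError("worker count W must be >= 1")
    out: List[List[T]] = [[] for _ in range(W)]
    for i, item in enumerate(items):
        out[i % W].append(item)
    return out


def cyclic_merge(parts: Sequence[Sequence[T]]) -> List[T]:
    """Exact inverse of :func:`cyclic_divide`."""
    W = len(parts)
    total = sum(len(p) for p in parts)
    out: List[T] = []
    iters = [iter(p) for p in parts]
    for i in range(total):
        try:
            out.append(next(iters[i % W]))
        except StopIteration:
            raise CorruptionError("cyclic parts have inconsistent sizes") from None
    return out
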