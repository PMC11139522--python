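"""Synthetic QSD generation and evaluation metrics.

Real quality-score data falls into two regimes: modern short-read
instruments emit binned qualities (a handful of distinct symbols with
long runs and mild position-dependent degradation), while long-read
platforms emit a wide alphabet (~40-64 symbols) with much weaker run
structure and highly variable record lengths.  The generator emulates
both with a first-order Markov chain: the first symbol of a record is
drawn from a stationary distribution (shifted by a positional drift
term), and each subsequent symbol repeats its predecessor with the
"stay" probability ``p`` or is redrawn from the stationary law at its
position.

What this captures: run persistence, alphabet size, positional quality
drift, variable lengths.  What it does not: instrument-specific cycle
artefacts, correlation between quality and base identity, or tile-level
structure of real flow cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

from .qsd_io import MAX_CODE, QsdBlock, QualityRecord


@dataclass(frozen=True)
class QsdProfile:
    """A reproducible recipe for one synthetic QSD corpus."""

    name: str
    alphabet_size: int
    stay_probability: float
    m: int
    stationary: Optional[Tuple[float, ...]] = None  # None = uniform
    drift_slope: float = 0.0  # symbols per position, applied at draw time
    fixed_length: Optional[int] = 100
    length_range: Optional[Tuple[int, int]] = None
    base_code: int = 0  # alphabet occupies codes [base_code, base_code + A)
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.stay_probability <= 1.0:
            raise ValueError("stay probability must be in [0, 1]")
        if not 1 <= self.alphabet_size <= MAX_CODE + 1:
            raise ValueError("alphabet size must be in [1, 94]")
        if self.base_code + self.alphabet_size - 1 > MAX_CODE:
            raise ValueError("alphabet exceeds the Phred+33 code range")
        if (self.fixed_length is None) == (self.length_range is None):
            raise ValueError("give exactly one of fixed_length, length_range")
        if self.stationary is not None:
            if len(self.stationary) != self.alphabet_size:
                raise ValueError("stationary distribution size != alphabet size")
            if any(w < 0 for w in self.stationary) or not math.isclose(
                    sum(self.stationary), 1.0, abs_tol=1e-9):
                raise ValueError("stationary weights must be a distribution")

    def with_(self, **kwargs) -> "QsdProfile":
        return replace(self, **kwargs)


def _ramp(A: int) -> Tuple[float, ...]:
    w = np.arange(1, A + 1, dtype=float)
    return tuple(w / w.sum())


#: Bundled corpora profiles spanning the short/long-read regimes.
PROFILES: Dict[str, QsdProfile] = {
    "binned-short": QsdProfile(
        name="binned-short", alphabet_size=4, stay_probability=0.9,
        m=1000, fixed_length=100, base_code=2),
    "hiseq-short": QsdProfile(
        name="hiseq-short", alphabet_size=40, stay_probability=0.6,
        m=1000, fixed_length=100, stationary=_ramp(40), drift_slope=-0.05),
    "long-read": QsdProfile(
        name="long-read", alphabet_size=64, stay_probability=0.4,
        m=40, fixed_length=None, length_range=(500, 20_000)),
    "adversarial-iid": QsdProfile(
        name="adversarial-iid", alphabet_size=94, stay_probability=0.0,
        m=1000, fixed_length=100),
}


def generate_qsd(profile: QsdProfile) -> QsdBlock:
    """Draw a QSD block from a profile; fully determined by the seed."""
    rng = np.random.default_rng(profile.seed)
    A = profile.alphabet_size
    p = profile.stay_probability
    stationary = (np.asarray(profile.stationary)
                  if profile.stationary is not None
                  else np.full(A, 1.0 / A))
    records = []
    for i in range(profile.m):
        if profile.fixed_length is not None:
            L = profile.fixed_length
        else:
            lo, hi = profile.length_range
            L = int(rng.integers(lo, hi + 1))
        if L == 0:
            records.append(QualityRecord(symbols=[], index=i))
            continue
        pos = np.arange(L)
        base = rng.choice(A, size=L, p=stationary)
        drifted = np.clip(
            base + np.floor(profile.drift_slope * pos).astype(np.int64),
            0, A - 1)
        stay = rng.random(L) < p
        stay[0] = False  # first symbol is always a fresh draw
        anchor = np.where(~stay, pos, -1)
        last_anchor = np.maximum.accumulate(anchor)
        symbols = (drifted[last_anchor] + profile.base_code).tolist()
        records.append(QualityRecord(symbols=symbols, index=i))
    return QsdBlock(records=records)


def conditional_entropy(profile: QsdProfile) -> float:
    """Exact per-symbol conditional entropy H(next | prev), in bits.

    Valid for drift-free profiles: next equals prev with probability
    p + (1-p) * pi(prev), otherwise symbol s with probability (1-p) * pi(s).
    """
    A = profile.alphabet_size
    p = profile.stay_probability
    pi = (np.asarray(profile.stationary)
          if profile.stationary is not None else np.full(A, 1.0 / A))
    H = 0.0
    for c in range(A):
        probs = (1.0 - p) * pi.copy()
        probs[c] += p
        nz = probs[probs > 0]
        H += pi[c] * float(-(nz * np.log2(nz)).sum())
    return H


def compression_ratio(compressed_bytes: int, total_chars: int) -> float:
    """Bits per base: 8 x compressed bytes / number of QSD characters."""
    if total_chars < 1:
        raise ValueError("compression ratio needs at least one character")
    return 8.0 * compressed_bytes / total_chars


def robustness_cv(ratios: Sequence[float]) -> float:
    """Coefficient of variation of per-dataset ratios, as a percentage.

    Population (not sample) standard deviation; lower means performance
    is less sensitive to the data distribution.
    """
    if len(ratios) < 2:
        raise ValueError("CV needs at least two ratios")
    arr = np.asarray(ratios, dtype=float)
    mean = arr.mean()
    if mean <= 0:
        raise ValueError("CV needs a positive mean ratio")
    return 100.0 * float(arr.std(ddof=0)) / float(mean)


def weighted_avg_ratio(ratios: Sequence[float],
                       sizes: Sequence[float]) -> float:
    """File-size-weighted average compression ratio."""
    if len(ratios) != len(sizes):
        raise ValueError("ratios and sizes must have equal counts")
    if not ratios:
        raise ValueError("need at least one ratio")
    if any(s <= 0 for s in sizes):
        raise ValueError("sizes must be positive")
    r = np.asarray(ratios, dtype=float)
    w = np.asarray(sizes, dtype=float)
    return float((r * w).sum() / w.sum())
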