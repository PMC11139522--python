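"""Entropy-coding backend.

The workhorse is a self-contained adaptive arithmetic coder: a 32-bit
range coder (carry-propagating, LZMA-style renormalization) driven by an
order-0/1/2 context model with per-context symbol counts.  Counts start
at 1 for every alphabet symbol, grow by a fixed increment of 32 per coded
symbol, and are halved (floored at 1) when a context's total exceeds
2^16; these constants are fixed so payloads are bit-reproducible across
platforms.  General-purpose codecs (zlib, bz2, lzma) are available as
plug-ins behind the same dispatch interface; integer streams are
serialized as LEB128 variable-length bytes before byte-oriented codecs.
"""

from __future__ import annotations

import bz2
import lzma
import zlib
from typing import Dict, List, Sequence

from .qsd_io import AlphabetError, CorruptionError

MASK32 = 0xFFFFFFFF
TOP = 1 << 24
INCREMENT = 32
RESCALE_LIMIT = 1 << 16

CODEC_IDS = {"ac0": 0, "ac1": 1, "ac2": 2, "store": 3, "gp1": 4, "gp2": 5, "gp3": 6}
CODEC_NAMES = {v: k for k, v in CODEC_IDS.items()}
_GP_MODULES = {"gp1": zlib, "gp2": bz2, "gp3": lzma}


class _Model:
    """Adaptive per-context frequency model shared by encoder and decoder."""

    __slots__ = ("alphabet_size", "order", "contexts")

    def __init__(self, alphabet_size: int, order: int):
        if not 0 <= order <= 2:
            raise ValueError("model order must be 0, 1 or 2")
        if not 1 <= alphabet_size <= 256:
            raise ValueError("alphabet size must be in [1, 256]")
        self.alphabet_size = alphabet_size
        self.order = order
        self.contexts: Dict[tuple, List[int]] = {}

    def counts(self, ctx: tuple) -> List[int]:
        c = self.contexts.get(ctx)
        if c is None:
            # slot -1 caches the context total
            c = [1] * self.alphabet_size + [self.alphabet_size]
            self.contexts[ctx] = c
        return c

    @staticmethod
    def update(c: List[int], sym: int) -> None:
        c[sym] += INCREMENT
        c[-1] += INCREMENT
        if c[-1] > RESCALE_LIMIT:
            total = 0
            for i in range(len(c) - 1):
                v = c[i] >> 1
                if v < 1:
                    v = 1
                c[i] = v
                total += v
            c[-1] = total


def _context_of(history: tuple, order: int) -> tuple:
    if order == 0:
        return ()
    return history[-order:]


class _RangeEncoder:
    """Carry-propagating 32-bit range encoder (LZMA-style shift_low)."""

    def __init__(self):
        self.low = 0
        self.range = MASK32
        self.cache = 0
        self.cache_size = 1  # first emitted byte is a dummy
        self.out = bytearray()

    def encode(self, cum: int, freq: int, total: int) -> None:
        r = self.range // total
        self.low += r * cum
        self.range = r * freq
        while self.range < TOP:
            self._shift_low()
            self.range = (self.range << 8) & MASK32

    def _shift_low(self) -> None:
        if self.low < 0xFF000000 or self.low > MASK32:
            carry = self.low >> 32
            self.out.append((self.cache + carry) & 0xFF)
            for _ in range(self.cache_size - 1):
                self.out.append((0xFF + carry) & 0xFF)
            self.cache_size = 0
            self.cache = (self.low >> 24) & 0xFF
        self.cache_size += 1
        self.low = (self.low << 8) & MASK32

    def finish(self) -> bytes:
        for _ in range(5):
            self._shift_low()
        return bytes(self.out)


class _RangeDecoder:
    def __init__(self, payload: bytes):
        self.payload = payload
        self.pos = 1  # skip the encoder's dummy byte
        self.range = MASK32
        self.code = 0
        for _ in range(4):
            self.code = (self.code << 8) | self._next_byte()

    def _next_byte(self) -> int:
        if self.pos >= len(self.payload):
            raise CorruptionError("arithmetic payload truncated")
        b = self.payload[self.pos]
        self.pos += 1
        return b

    def decode(self, counts: List[int]) -> int:
        """Find the symbol covering the current code point and consume it."""
        total = counts[-1]
        r = self.range // total
        target = self.code // r
        if target >= total:
            target = total - 1
        acc = 0
        sym = 0
        for i in range(len(counts) - 1):
            nxt = acc + counts[i]
            if target < nxt:
                sym = i
                break
            acc = nxt
        else:
            raise CorruptionError("arithmetic payload corrupt: bad target")
        self.code -= r * acc
        self.range = r * counts[sym]
        while self.range < TOP:
            self.code = ((self.code << 8) | self._next_byte()) & MASK32
            self.range = (self.range << 8) & MASK32
        return sym


def ac_encode(stream: Sequence[int], alphabet_size: int, order: int) -> bytes:
    """Adaptive arithmetic coding of a symbol stream."""
    model = _Model(alphabet_size, order)
    enc = _RangeEncoder()
    if not len(stream):
        return b""
    history: tuple = ()
    for sym in stream:
        if not 0 <= sym < alphabet_size:
            raise AlphabetError(f"symbol {sym} outside alphabet [0, {alphabet_size})")
        c = model.counts(_context_of(history, order))
        cum = sum(c[:sym])
        enc.encode(cum, c[sym], c[-1])
        model.update(c, sym)
        if order:
            history = (history + (sym,))[-order:]
    return enc.finish()


def ac_decode(payload: bytes, n: int, alphabet_size: int, order: int) -> List[int]:
    """Exact inverse of :func:`ac_encode`; model evolution mirrors encoding."""
    if n == 0:
        return []
    model = _Model(alphabet_size, order)
    dec = _RangeDecoder(payload)
    out: List[int] = []
    history: tuple = ()
    for _ in range(n):
        c = model.counts(_context_of(history, order))
        sym = dec.decode(c)
        model.update(c, sym)
        out.append(sym)
        if order:
            history = (history + (sym,))[-order:]
    return out


def leb128_encode(values: Sequence[int]) -> bytes:
    out = bytearray()
    for v in values:
        if v < 0:
            raise ValueError("LEB128 serializer takes non-negative integers")
        while True:
            byte = v & 0x7F
            v >>= 7
            if v:
                out.append(byte | 0x80)
            else:
                out.append(byte)
                break
    return bytes(out)


def leb128_decode(data: bytes, n: int) -> List[int]:
    out: List[int] = []
    v = 0
    shift = 0
    for byte in data:
        v |= (byte & 0x7F) << shift
        if byte & 0x80:
            shift += 7
        else:
            out.append(v)
            v = 0
            shift = 0
    if shift:
        raise CorruptionError("LEB128 stream ends mid-value")
    if len(out) != n:
        raise CorruptionError(f"LEB128 stream decoded {len(out)} values, expected {n}")
    return out


def compress_stream(stream: Sequence[int], codec: str,
                    alphabet_size: int | None = None) -> bytes:
    """Dispatch a symbol/integer stream to the named codec."""
    if codec not in CODEC_IDS:
        raise ValueError(f"unknown codec {codec!r}")
    if codec.startswith("ac"):
        if alphabet_size is None:
            raise ValueError("arithmetic codecs need an alphabet size")
        return ac_encode(stream, alphabet_size, int(codec[2]))
    raw = leb128_encode(stream)
    if codec == "store":
        return raw
    return _GP_MODULES[codec].compress(raw)


def decompress_stream(payload: bytes, codec: str, n: int,
                      alphabet_size: int | None = None) -> List[int]:
    """Exact inverse of :func:`compress_stream`."""
    if codec not in CODEC_IDS:
        raise ValueError(f"unknown codec {codec!r}")
    if codec.startswith("ac"):
        if alphabet_size is None:
            raise ValueError("arithmetic codecs need an alphabet size")
        return ac_decode(payload, n, alphabet_size, int(codec[2]))
    if codec == "store":
        raw = payload
    else:
        try:
            raw = _GP_MODULES[codec].decompress(payload)
        except Exception as exc:
            raise CorruptionError(f"{codec} payload corrupt: {exc}") from exc
    return leb128_decode(raw, n)
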