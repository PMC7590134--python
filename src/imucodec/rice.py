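"""Golomb-Rice coding of prediction residuals.

Residuals from a good predictor are small, zero-centred and roughly
two-sided geometric. They are mapped to unsigned integers with the
zigzag bijection (small magnitudes keep small codes regardless of sign)
and Rice-coded: value u splits into quotient q = u >> m (unary coded,
q ones + a zero) and an m-bit binary remainder, for a codeword of
exactly m + q + 1 bits. Rice codes are near-optimal for geometric
inputs and need no symbol table.

An escape path bounds worst-case expansion: a quotient above
``ESCAPE_QUOTIENT`` is emitted as 48 one-bits followed by the raw value
in 32 bits, so one adversarial sample cannot blow up the stream.
"""

from __future__ import annotations

import numpy as np

MAX_RICE_ORDER = 15        # search range for static order selection
RICE_ORDER_LIMIT = 30      # hard validity cap
ESCAPE_QUOTIENT = 47
_ESCAPE_ONES = (1 << 48) - 1
_ESCAPE_BITS = 48 + 32


class TruncatedStreamError(ValueError):
    """Bitstream ended inside a codeword."""


class BitWriter:
    """Append-order bitstream, bytes filled most-significant-bit first."""

    __slots__ = ("_buf", "_acc", "_nbits")

    def __init__(self) -> None:
        self._buf = bytearray()
        self._acc = 0
        self._nbits = 0

    def write_bits(self, value: int, n: int) -> None:
        if n == 0:
            return
        self._acc = (self._acc << n) | (value & ((1 << n) - 1))
        self._nbits += n
        while self._nbits >= 8:
            self._nbits -= 8
            self._buf.append((self._acc >> self._nbits) & 0xFF)
        self._acc &= (1 << self._nbits) - 1

    def write_unary(self, q: int) -> None:
        """q one-bits followed by a zero terminator."""
        while q >= 32:
            self.write_bits(0xFFFFFFFF, 32)
            q -= 32
        self.write_bits(((1 << q) - 1) << 1, q + 1)

    @property
    def bit_length(self) -> int:
        return 8 * len(self._buf) + self._nbits

    def getvalue(self) -> bytes:
        """Byte string, zero-padded to a byte boundary."""
        out = bytearray(self._buf)
        if self._nbits:
            out.append((self._acc << (8 - self._nbits)) & 0xFF)
        return bytes(out)


class BitReader:
    """MSB-first reader over a byte string."""

    __slots__ = ("_data", "_pos", "_nbits")

    def __init__(self, data: bytes) -> None:
        self._data = data
        self._pos = 0
        self._nbits = 8 * len(data)

    def read_bit(self) -> int:
        if self._pos >= self._nbits:
            raise TruncatedStreamError("bitstream exhausted")
        byte = self._data[self._pos >> 3]
        bit = (byte >> (7 - (self._pos & 7))) & 1
        self._pos += 1
        return bit

    def read_bits(self, n: int) -> int:
        if self._pos + n > self._nbits:
            raise TruncatedStreamError("bitstream exhausted")
        value = 0
        for _ in range(n):
            byte = self._data[self._pos >> 3]
            value = (value << 1) | ((byte >> (7 - (self._pos & 7))) & 1)
            self._pos += 1
        return value


def zigzag(e: int) -> int:
    """Map a signed residual to an unsigned code index: 0,-1,1,-2,2 -> 0,1,2,3,4."""
    return 2 * e if e >= 0 else -2 * e - 1


def unzigzag(u: int) -> int:
    return (u >> 1) if (u & 1) == 0 else -((u + 1) >> 1)


def zigzag_array(e: np.ndarray) -> np.ndarray:
    e = np.asarray(e, dtype=np.int64)
    return np.where(e >= 0, 2 * e, -2 * e - 1).astype(np.uint64)


def unzigzag_array(u: np.ndarray) -> np.ndarray:
    u = np.asarray(u, dtype=np.int64)
    return np.where(u & 1 == 0, u >> 1, -((u + 1) >> 1))


def rice_codeword_length(u: int, m: int) -> int:
    """Bits of the codeword for unsigned u at order m: m + floor(u/2^m) + 1
    (the escape codeword is a fixed 80 bits)."""
    q = u >> m
    return _ESCAPE_BITS if q > ESCAPE_QUOTIENT else m + q + 1


def rice_encode_value(u: int, m: int, out: BitWriter) -> int:
    """Append one Rice codeword; returns the number of bits written."""
    if u < 0:
        raise ValueError("Rice coding takes unsigned values; zigzag first")
    if not (0 <= m <= RICE_ORDER_LIMIT):
        raise ValueError(f"Rice order {m} outside [0, {RICE_ORDER_LIMIT}]")
    q = u >> m
    if q > ESCAPE_QUOTIENT:
        out.write_bits(_ESCAPE_ONES, 48)
        out.write_bits(u, 32)
        return _ESCAPE_BITS
    out.write_unary(q)
    if m:
        out.write_bits(u & ((1 << m) - 1), m)
    return m + q + 1


def rice_decode_value(reader: BitReader, m: int) -> int:
    """Inverse of ``rice_encode_value``, including the escape path."""
    q = 0
    while reader.read_bit():
        q += 1
        if q == ESCAPE_QUOTIENT + 1:
            return reader.read_bits(32)
    return (q << m) | (reader.read_bits(m) if m else 0)


def select_rice_order(residuals: np.ndarray) -> int:
    """Static Rice order minimizing the total closed-form codeword cost.

    Exhaustive two-pass search over m in [0, 15]; the cost of order m is
    sum(m + u>>m + 1) over the zigzagged residuals. Ties break toward
    smaller m.
    """
    residuals = np.asarray(residuals)
    if residuals.size == 0:
        raise ValueError("cannot pick a Rice order for an empty residual block")
    us = zigzag_array(residuals).astype(np.int64)
    costs = [
        residuals.size * (m + 1) + int(np.sum(us >> m))
        for m in range(MAX_RICE_ORDER + 1)
    ]
    return int(np.argmin(costs))


def heuristic_rice_order(residuals: np.ndarray) -> int:
    """One-pass streaming heuristic: m = floor(log2(max(1, mean u)))."""
    us = zigzag_array(residuals).astype(np.int64)
    mean = max(1.0, float(us.mean())) if us.size else 1.0
    return min(MAX_RICE_ORDER, int(np.floor(np.log2(mean))))


def streaming_rice_orders(residuals: np.ndarray, window: int = 64) -> np.ndarray:
    """Causal per-sample order estimates over a trailing window (diagnostic;
    the shipped container always uses one static order per channel block)."""
    us = zigzag_array(residuals).astype(np.float64)
    orders = np.zeros(us.size, dtype=np.int64)
    csum = np.concatenate([[0.0], np.cumsum(us)])
    for n in range(us.size):
        lo = max(0, n - window)
        mean = (csum[n] - csum[lo]) / max(1, n - lo) if n > lo else 1.0
        orders[n] = min(MAX_RICE_ORDER, int(np.floor(np.log2(max(1.0, mean)))))
    return orders


def encode_residuals(residuals: np.ndarray, m: int) -> tuple[bytes, int]:
    """Rice-encode a residual block; returns (payload bytes, exact bit count).

    The returned bit count is asserted against the closed-form length law
    for every non-escape codeword.
    """
    out = BitWriter()
    total = 0
    for e in np.asarray(residuals, dtype=np.int64).tolist():
        u = zigzag(e)
        written = rice_encode_value(u, m, out)
        if (u >> m) <= ESCAPE_QUOTIENT:
            assert written == m + (u >> m) + 1
        total += written
    assert total == out.bit_length
    return out.getvalue(), total


def decode_residuals(payload: bytes, count: int, m: int) -> np.ndarray:
    """Decode ``count`` residuals from a Rice payload."""
    reader = BitReader(payload)
    return np.array(
        [unzigzag(rice_decode_value(reader, m)) for _ in range(count)],
        dtype=np.int64,
    )
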