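"""Q16.16 signed fixed-point arithmetic.

Prediction must be bit-identical on the encoder and the decoder, on any
platform: IEEE-754 floating point cannot guarantee that, so all predictor
evaluation is done in 32-bit signed Q16.16 fixed point (16 integer bits,
16 fractional bits) with exact 64-bit integer accumulation.

Only the operations prediction needs are provided: coefficient
quantization and a fused multiply-accumulate dot product.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

FRAC_BITS = 16
ONE_RAW = 1 << FRAC_BITS          # 1.0 in Q16.16
RAW_MIN = -(1 << 31)
RAW_MAX = (1 << 31) - 1
VALUE_MIN = RAW_MIN / ONE_RAW     # -32768.0
VALUE_MAX = RAW_MAX / ONE_RAW     # 32767.99998474...

# history lengths are capped so that sum(|coeff_raw| * |int16|) over p terms
# stays well inside a signed 64-bit accumulator
MAX_TERMS = 64


class FixedPointOverflowError(OverflowError):
    """Value outside the representable Q16.16 range."""


@dataclass(frozen=True)
class Q16_16:
    """A Q16.16 fixed-point number: value = raw / 2**16.

    ``raw`` is a 32-bit signed integer; the representable range is
    [-32768.0, 32767.99998474] with a resolution of 2**-16.
    """

    raw: int

    def __post_init__(self) -> None:
        if not (RAW_MIN <= self.raw <= RAW_MAX):
            raise FixedPointOverflowError(
                f"raw value {self.raw} outside 32-bit signed range"
            )

    @property
    def value(self) -> float:
        return self.raw / ONE_RAW

    @classmethod
    def from_int(cls, n: int) -> "Q16_16":
        return cls(int(n) << FRAC_BITS)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Q16_16({self.value!r})"


def quantize(value: float) -> Q16_16:
    """Quantize a real number to Q16.16, rounding half away from zero.

    Round-half-away-from-zero treats positive and negative coefficients
    symmetrically. The quantization error is at most 2**-17.

    Raises
    ------
    FixedPointOverflowError
        If ``value`` falls outside the representable range.
    """
    if not math.isfinite(value):
        raise FixedPointOverflowError(f"cannot quantize {value!r}")
    scaled = abs(value) * ONE_RAW
    raw = int(math.floor(scaled + 0.5))
    if value < 0:
        raw = -raw
    if not (RAW_MIN <= raw <= RAW_MAX):
        raise FixedPointOverflowError(
            f"value {value!r} outside Q16.16 range [{VALUE_MIN}, {VALUE_MAX}]"
        )
    return Q16_16(raw)


def quantize_vector(values: Iterable[float]) -> tuple[Q16_16, ...]:
    return tuple(quantize(v) for v in values)


def raw_array(coeffs: Sequence[Q16_16]) -> np.ndarray:
    """Raw Q16.16 words of a coefficient vector as an int64 array."""
    return np.array([c.raw for c in coeffs], dtype=np.int64)


def fma_dot(coeffs: Sequence[Q16_16], samples: Sequence[int]) -> int:
    """Exact fixed-point dot product: floor(sum(coeff.raw * sample) / 2**16).

    The accumulation is exact wide-integer multiply-accumulate; the final
    arithmetic right shift truncates toward -infinity. One fixed rounding
    convention is what lets the decoder reproduce the encoder's predictions
    bit for bit; floor matches two's-complement shift semantics.

    For integer-valued coefficients the result equals the plain integer dot
    product exactly (no rounding at all).
    """
    if len(coeffs) != len(samples):
        raise ValueError(
            f"length mismatch: {len(coeffs)} coefficients vs {len(samples)} samples"
        )
    if len(coeffs) > MAX_TERMS:
        raise ValueError(f"at most {MAX_TERMS} terms supported, got {len(coeffs)}")
    acc = 0
    for c, s in zip(coeffs, samples):
        acc += c.raw * int(s)
    return acc >> FRAC_BITS


def fma_dot_raw(raw_coeffs: np.ndarray, windows: np.ndarray) -> np.ndarray:
    """Vectorized ``fma_dot`` over rows of past-sample windows.

    ``raw_coeffs`` are int64 Q16.16 raw words ordered most-recent-first and
    ``windows`` is an (n, p) int64 array whose row n holds
    [x[n-1], ..., x[n-p]]. Returns the integer predictions as int64.

    numpy's right_shift on signed integers is arithmetic, so this matches
    the scalar floor semantics exactly.
    """
    acc = windows @ raw_coeffs
    return acc >> FRAC_BITS
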