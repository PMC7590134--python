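"""Autoregressive linear predictors for IMU sample streams.

Every model shipped here — delta coding, linear extrapolation, 2nd–5th
order polynomial regression, and natural cubic-spline extrapolation —
reduces to a fixed causal linear filter over the previous ``p`` samples:

    x_hat[n] = sum_k a_k * x[n-k],   k = 1..p

The filter weights are derived once in real arithmetic, quantized to
Q16.16, and then applied with exact integer arithmetic so that the
encoder and decoder agree bit for bit. The quantity actually entropy
coded is the residual e[n] = x[n] - x_hat[n].

Why these models: a slowly varying signal is nearly constant over one
sample period (delta), locally linear (linear extrapolation), or locally
polynomial; the spline variant extrapolates the minimum-curvature cubic
through the recent past, which avoids the oscillatory blow-up
(Runge's phenomenon) of high-order polynomial extrapolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.interpolate import CubicSpline

from .fixedpoint import (
    FRAC_BITS,
    ONE_RAW,
    Q16_16,
    fma_dot_raw,
    quantize,
    raw_array,
)

INT16_MIN = -32768
INT16_MAX = 32767

#: canonical method names accepted throughout the package / CLI
METHOD_NAMES = ("delta", "linear", "poly2", "poly3", "poly4", "poly5", "spline")

DEFAULT_SPLINE_KNOTS = 5


class CorruptStreamError(ValueError):
    """Decoding produced a sample outside the 16-bit range."""


def _check_int16(samples: np.ndarray, what: str = "sample") -> None:
    if samples.size and (samples.min() < INT16_MIN or samples.max() > INT16_MAX):
        bad = samples[(samples < INT16_MIN) | (samples > INT16_MAX)][0]
        raise ValueError(f"{what} {int(bad)} outside 16-bit signed range")


@dataclass(frozen=True)
class SignalChannel:
    """One stream of 16-bit signed integer samples at a fixed rate."""

    samples: np.ndarray
    rate_hz: float = 60.0
    label: str = ""

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.int64)
        if samples.ndim != 1 or samples.size < 1:
            raise ValueError("a channel is a non-empty 1-D sample sequence")
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")
        _check_int16(samples)
        object.__setattr__(self, "samples", samples)

    def __len__(self) -> int:
        return int(self.samples.size)


@dataclass(frozen=True)
class PredictorSpec:
    """A named fixed linear predictor.

    ``coeffs`` are Q16.16 weights ordered most-recent-first: coeffs[0]
    multiplies x[n-1]. ``d`` is the polynomial order (ignored for spline
    and custom specs); ``p`` the history length.
    """

    method: str
    d: int
    p: int
    coeffs: tuple[Q16_16, ...] = field(repr=False)

    def __post_init__(self) -> None:
        if self.method not in ("delta", "poly", "spline", "custom"):
            raise ValueError(f"unknown method {self.method!r}")
        if len(self.coeffs) != self.p:
            raise ValueError("coefficient vector length must equal p")
        if self.method == "delta" and (self.p != 1 or self.coeffs[0].raw != ONE_RAW):
            raise ValueError("delta predictor is p=1 with unit coefficient")

    @property
    def name(self) -> str:
        if self.method == "delta":
            return "delta"
        if self.method == "poly":
            return "linear" if self.d == 1 else f"poly{self.d}"
        return self.method

    def raw_coeffs(self) -> np.ndarray:
        return raw_array(self.coeffs)


@dataclass(frozen=True)
class ResidualStream:
    """Prediction residuals plus the verbatim warm-up samples.

    The first ``p`` samples are stored verbatim so the decoder has
    history to run the predictor; the warm-up is shorter than ``p`` only
    for signals shorter than ``p`` (stored entirely as warm-up).
    """

    warmup: np.ndarray
    residuals: np.ndarray
    p: int

    def __post_init__(self) -> None:
        warmup = np.asarray(self.warmup, dtype=np.int64)
        residuals = np.asarray(self.residuals, dtype=np.int64)
        if len(warmup) > self.p:
            raise ValueError("warm-up longer than history length")
        if len(warmup) < self.p and len(residuals):
            raise ValueError("short warm-up is only valid for residual-free streams")
        object.__setattr__(self, "warmup", warmup)
        object.__setattr__(self, "residuals", residuals)

    def __len__(self) -> int:
        return int(self.warmup.size + self.residuals.size)


# ---------------------------------------------------------------------------
# coefficient derivation


def derive_poly_coeffs(d: int, p: int) -> np.ndarray:
    """Weights of the one-step order-``d`` polynomial extrapolator over
    ``p`` past samples, most-recent-first.

    A degree-d polynomial is least-squares fitted to the past samples at
    positions -1..-p and evaluated at 0; because the positions are fixed,
    the whole fit-and-evaluate collapses into one precomputable filter
    row e_0 (C^T C)^{-1} C^T with C[i-1, j] = (-i)^j.

    For the exact-fit case p = d+1 the weights are the alternating
    binomial coefficients of forward extrapolation — integers, hence
    exactly representable in Q16.16.
    """
    if d < 0 or p <= d:
        raise ValueError("need history length p > polynomial order d >= 0")
    if p > 64:
        raise ValueError("history length capped at 64")
    if p == d + 1:
        # finite-difference extrapolation: x_hat[n] = sum (-1)^(k+1) C(d+1,k) x[n-k]
        return np.array(
            [((-1) ** k) * comb(d + 1, k + 1) for k in range(p)], dtype=float
        )
    positions = -np.arange(1, p + 1, dtype=float)        # x[n-1] ... x[n-p]
    C = np.vander(positions, d + 1, increasing=True)     # C[i, j] = (-i-1)^j
    gram = C.T @ C
    weights = np.linalg.solve(gram, C.T)[0]              # row for the t=0 value
    if not np.isfinite(weights).all():                   # pragma: no cover
        raise np.linalg.LinAlgError("rank-deficient polynomial design")
    return weights


def derive_spline_coeffs(p: int) -> np.ndarray:
    """Weights of the natural-cubic-spline one-step extrapolator over
    ``p`` knots at unit spacing, most-recent-first.

    The spline through the p most recent samples is linear in the data,
    so extrapolating its last cubic piece one step past the final knot
    is again a fixed linear combination of the samples; the weights are
    obtained by feeding unit impulses through the spline construction.
    Natural boundary conditions (zero second derivative at both end
    knots) make the extrapolator exact on constants and straight lines.
    """
    if p < 3:
        raise ValueError("spline extrapolation needs at least 3 knots")
    if p > 16:
        raise ValueError("spline history capped at 16 knots")
    knots = np.arange(p, dtype=float)
    weights_by_position = np.empty(p)
    for j in range(p):
        impulse = np.zeros(p)
        impulse[j] = 1.0
        cs = CubicSpline(knots, impulse, bc_type="natural", extrapolate=True)
        weights_by_position[j] = cs(float(p))
    # position p-1 is x[n-1]; reverse to most-recent-first
    return weights_by_position[::-1].copy()


def _quantize_predictor_coeffs(weights: np.ndarray) -> tuple[Q16_16, ...]:
    """Quantize filter weights to Q16.16 and renormalize the raw sum to
    exactly 2**16.

    Every derived predictor has weights summing to 1 (it must reproduce
    constants); independent rounding can leave the raw sum off by a few
    ticks, which turns into a nonzero residual on large constant inputs.
    The rounding correction is folded into the most-recent weight.
    """
    qs = [quantize(w) for w in weights]
    drift = ONE_RAW - sum(q.raw for q in qs)
    if drift:
        qs[0] = Q16_16(qs[0].raw + drift)
    return tuple(qs)


# ---------------------------------------------------------------------------
# spec factories


def delta_spec() -> PredictorSpec:
    return PredictorSpec("delta", 0, 1, (Q16_16(ONE_RAW),))

def poly_spec(d: int, p: int | None = None) -> PredictorSpec:
    """Order-``d`` polynomial predictor; default history is the exact fit
    p = d+1 (integer weights, zero quantization error)."""
    if p is None:
        p = d + 1
    if d == 0 and p == 1:
        return delta_spec()
    return PredictorSpec("poly", d, p, _quantize_predictor_coeffs(derive_poly_coeffs(d, p)))

def spline_spec(p: int = DEFAULT_SPLINE_KNOTS) -> PredictorSpec:
    return PredictorSpec("spline", 3, p, _quantize_predictor_coeffs(derive_spline_coeffs(p)))

def custom_spec(coeffs: Sequence[Q16_16]) -> PredictorSpec:
    return PredictorSpec("custom", 0, len(coeffs), tuple(coeffs))


def predictor_from_name(name: str, p: int | None = None) -> PredictorSpec:
    """Resolve a CLI-style method name to a PredictorSpec."""
    if name == "delta":
        return delta_spec()
    if name == "linear":
        return poly_spec(1, p)
    if name.startswith("poly") and name[4:].isdigit():
        return poly_spec(int(name[4:]), p)
    if name == "spline":
        return spline_spec(p if p is not None else DEFAULT_SPLINE_KNOTS)
    raise ValueError(f"unknown method {name!r}; expected one of {METHOD_NAMES}")


# ---------------------------------------------------------------------------
# encode / decode


def predict_encode(channel: SignalChannel, spec: PredictorSpec) -> ResidualStream:
    """Run the predictor causally over the channel and return residuals.

    The filter has zero delay: the prediction for sample n uses samples
    n-1..n-p only. Signals shorter than p are stored entirely as warm-up.
    """
    x = channel.samples
    p = spec.p
    if len(x) <= p:
        return ResidualStream(x.copy(), np.empty(0, dtype=np.int64), p)
    windows = sliding_window_view(x, p)[:-1][:, ::-1]    # row n-p: [x[n-1]..x[n-p]]
    preds = fma_dot_raw(spec.raw_coeffs(), np.ascontiguousarray(windows))
    return ResidualStream(x[:p].copy(), x[p:] - preds, p)


def predict_decode(stream: ResidualStream, spec: PredictorSpec) -> SignalChannel:
    """Invert ``predict_encode`` exactly.

    Each reconstructed sample is checked against the 16-bit range: an
    out-of-range value can only come from a corrupt or mismatched stream.
    """
    p = spec.p
    if stream.p != p:
        raise ValueError("residual stream history length does not match spec")
    out = [int(v) for v in stream.warmup]
    raws = [c.raw for c in spec.coeffs]
    for e in stream.residuals.tolist():
        acc = 0
        for k in range(p):
            acc += raws[k] * out[-1 - k]
        value = (acc >> FRAC_BITS) + e
        if not (INT16_MIN <= value <= INT16_MAX):
            raise CorruptStreamError(
                f"reconstructed sample {value} outside 16-bit range"
            )
        out.append(value)
    return SignalChannel(np.array(out, dtype=np.int64))
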