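"""The .kc compressed container and the baseline representations.

Container layout (all integers little-endian):

    fixed header, 16 bytes:
        magic   b"KC01"      4
        version 0x01         1
        method  id           1   (0 delta, 1 poly, 2 spline, 3 custom)
        d       poly order   1
        p       history      1
        s       channels     1
        l       samples      4
        reserved             3
    method 3 only: p Q16.16 coefficient raw words, 4 bytes each (signed)
    then per channel:
        m       Rice order   1
        warmup  min(p, l) int16 samples, 2 bytes each
        nbytes  payload size 4
        payload Rice bitstream, zero-padded to a byte boundary

Channels are predicted and coded independently; the file is fully
self-describing (the decoder needs no side information).

Baselines: a constant-width CSV dialect (the compression-ratio
reference, CR = 1 by definition), raw little-endian int16 binary, and
the DEFLATE size of the CSV at level 6.
"""

from __future__ import annotations

import struct
import zlib
from dataclasses import dataclass

import numpy as np

from .fixedpoint import Q16_16
from .predictors import (
    PredictorSpec,
    ResidualStream,
    SignalChannel,
    custom_spec,
    delta_spec,
    poly_spec,
    predict_decode,
    predict_encode,
    spline_spec,
)
from .rice import (
    decode_residuals,
    encode_residuals,
    heuristic_rice_order,
    select_rice_order,
)

MAGIC = b"KC01"
VERSION = 1
_METHOD_IDS = {"delta": 0, "poly": 1, "spline": 2, "custom": 3}
_METHOD_NAMES = {v: k for k, v in _METHOD_IDS.items()}
_HEADER = struct.Struct("<4sBBBBBI3x")   # 16 bytes
assert _HEADER.size == 16


class FormatError(ValueError):
    """Not a valid .kc container."""


@dataclass(frozen=True)
class CompressedBlock:
    """Parsed container: spec + per-channel Rice parameters and payloads."""

    spec: PredictorSpec
    n_channels: int
    n_samples: int
    rice_orders: tuple[int, ...]
    warmups: tuple[np.ndarray, ...]
    payloads: tuple[bytes, ...]


def compress_file(
    channels: list[SignalChannel],
    spec: PredictorSpec,
    rice_mode: str = "exhaustive",
) -> bytes:
    """Compress equal-length channels into one self-describing container.

    ``rice_mode`` selects the per-channel Rice order: "exhaustive"
    (default; two-pass search minimizing the block size) or "heuristic"
    (one-pass log2-of-mean estimate).
    """
    if not channels:
        raise ValueError("need at least one channel")
    if not (1 <= len(channels) <= 255):
        raise ValueError("channel count must be in [1, 255]")
    lengths = {len(c) for c in channels}
    if len(lengths) != 1:
        raise ValueError(f"channels have unequal lengths {sorted(lengths)}")
    (l,) = lengths
    if spec.p > 255:
        raise ValueError("history length does not fit the container header")

    pick_order = {"exhaustive": select_rice_order, "heuristic": heuristic_rice_order}
    if rice_mode not in pick_order:
        raise ValueError(f"unknown rice_mode {rice_mode!r}")

    out = bytearray(
        _HEADER.pack(MAGIC, VERSION, _METHOD_IDS[spec.method], spec.d, spec.p,
                     len(channels), l)
    )
    if spec.method == "custom":
        for c in spec.coeffs:
            out += struct.pack("<i", c.raw)

    for channel in channels:
        stream = predict_encode(channel, spec)
        m = pick_order[rice_mode](stream.residuals) if stream.residuals.size else 0
        payload, _ = encode_residuals(stream.residuals, m)
        out.append(m)
        out += np.asarray(stream.warmup, dtype="<i2").tobytes()
        out += struct.pack("<I", len(payload))
        out += payload
    return bytes(out)


def parse_block(data: bytes) -> CompressedBlock:
    """Validate and split a container without decoding the payloads."""
    if len(data) < _HEADER.size:
        raise FormatError("file shorter than the fixed header")
    magic, version, method_id, d, p, s, l = _HEADER.unpack_from(data, 0)
    if magic != MAGIC:
        raise FormatError(f"bad magic {magic!r}")
    if version != VERSION:
        raise FormatError(f"unsupported version {version}")
    if method_id not in _METHOD_NAMES:
        raise FormatError(f"unknown method id {method_id}")
    offset = _HEADER.size

    method = _METHOD_NAMES[method_id]
    if method == "custom":
        end = offset + 4 * p
        if end > len(data):
            raise FormatError("truncated coefficient table")
        raws = struct.unpack_from(f"<{p}i", data, offset)
        spec = custom_spec([Q16_16(r) for r in raws])
        offset = end
    elif method == "delta":
        spec = delta_spec()
    elif method == "poly":
        spec = poly_spec(d, p)
    else:
        spec = spline_spec(p)

    n_warm = min(p, l)
    orders, warmups, payloads = [], [], []
    for _ in range(s):
        if offset + 1 + 2 * n_warm + 4 > len(data):
            raise FormatError("truncated channel header")
        m = data[offset]
        offset += 1
        warm = np.frombuffer(data, dtype="<i2", count=n_warm, offset=offset)
        offset += 2 * n_warm
        (nbytes,) = struct.unpack_from("<I", data, offset)
        offset += 4
        if offset + nbytes > len(data):
            raise FormatError("truncated payload")
        payloads.append(data[offset : offset + nbytes])
        offset += nbytes
        orders.append(m)
        warmups.append(warm.astype(np.int64))
    if offset != len(data):
        raise FormatError(f"{len(data) - offset} trailing bytes after last payload")
    return CompressedBlock(spec, s, l, tuple(orders), tuple(warmups), tuple(payloads))


def decompress_file(data: bytes) -> list[SignalChannel]:
    """Decode a container back to the exact original channels."""
    block = parse_block(data)
    spec = block.spec
    channels = []
    for m, warm, payload in zip(block.rice_orders, block.warmups, block.payloads):
        n_res = block.n_samples - len(warm)
        residuals = decode_residuals(payload, n_res, m)
        stream = ResidualStream(warm, residuals, spec.p)
        channels.append(predict_decode(stream, spec))
    return channels


# ---------------------------------------------------------------------------
# baseline representations


def write_fixed_csv(channels: list[SignalChannel]) -> bytes:
    """Constant-width CSV: every value as sign + 5 zero-padded digits.

    One row per sample instant, channels as columns: 6 characters per
    value, comma separators, "\\n" line ends — exactly 7*s bytes per row,
    so the baseline size depends only on the shape of the data, never on
    its values.
    """
    if not channels:
        raise ValueError("need at least one channel")
    matrix = np.stack([c.samples for c in channels], axis=1)
    rows = ("," .join(f"{v:+06d}" for v in row) + "\n" for row in matrix.tolist())
    return "".join(rows).encode("ascii")


def read_fixed_csv(data: bytes, rate_hz: float = 60.0) -> list[SignalChannel]:
    rows = [line.split(",") for line in data.decode("ascii").splitlines()]
    matrix = np.array(rows, dtype=np.int64)
    return [SignalChannel(matrix[:, j], rate_hz=rate_hz) for j in range(matrix.shape[1])]


def write_binary(channels: list[SignalChannel]) -> bytes:
    """Row-interleaved little-endian int16: exactly 2*s*l bytes."""
    if not channels:
        raise ValueError("need at least one channel")
    matrix = np.stack([c.samples for c in channels], axis=1)
    return matrix.astype("<i2").tobytes()


def read_binary(data: bytes, n_channels: int, rate_hz: float = 60.0) -> list[SignalChannel]:
    flat = np.frombuffer(data, dtype="<i2").astype(np.int64)
    if flat.size % n_channels:
        raise ValueError("byte length not a multiple of the channel count")
    matrix = flat.reshape(-1, n_channels)
    return [SignalChannel(matrix[:, j], rate_hz=rate_hz) for j in range(n_channels)]


def deflate_size(data: bytes, level: int = 6) -> int:
    """Size of the DEFLATE-compressed input (the ZIP baseline's payload)."""
    return len(zlib.compress(data, level))
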