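"""Synthetic IMU corpora for testing and benchmarking without downloads.

The generator emulates the statistical shape of lower-body gait
recordings: six co-located 16-bit channels (3-axis accelerometer +
3-axis gyroscope) sampled at 60 Hz, in two regimes.

* ``active`` — quasi-periodic movement (walking/running-like): a
  harmonic series at the stride frequency (default 1.8 Hz, four
  harmonics with 1/h amplitude roll-off and random phases), plus one
  heel-strike impact transient per stride (a sharp two-to-three sample
  spike, timed identically on all co-located channels with per-channel
  polarity and scale), plus a broadband vibration floor (soft-tissue
  oscillation and unresolved high-frequency dynamics, scaling with
  movement intensity), plus Gaussian sensor noise. The broadband terms
  matter: a purely harmonic signal is band-limited well below the
  Nyquist rate and would be *better* predicted by high-order
  extrapolators, which real walking data — spectrally flat at high
  frequencies from impacts and vibration — is not.
* ``stationary`` — sitting/standing-like: a constant orientation offset
  plus small Gaussian sensor noise. First differences are a few LSB.

No biomechanical fidelity is claimed: the point is that the two regimes
reproduce the compressibility gap between stationary and active
movement and exercise every codec path (large amplitudes, clipping,
noise-dominated residuals).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import numpy as np

from .predictors import INT16_MAX, INT16_MIN, SignalChannel
from .io import TestCase

REGIMES = ("active", "stationary")

#: body segments mirroring a six-node lower-body sensor placement
SEGMENTS = (
    "left_foot", "right_foot",
    "left_shank", "right_shank",
    "left_thigh", "right_thigh",
)


@dataclass(frozen=True)
class SyntheticConfig:
    """Generation parameters for one test case.

    Amplitude and noise are in LSB of the 16-bit sample scale. A noise
    level of None picks the regime default (10 LSB active, 3 LSB
    stationary).
    """

    regime: str = "active"
    duration_s: float = 10.0
    rate_hz: float = 60.0
    channels: int = 6
    stride_hz: float = 1.8
    harmonics: int = 4
    amplitude: float = 8000.0
    impact_amplitude: float | None = None   # default: 2 x amplitude
    impact_decay: float = 0.35              # per-sample decay of the transient
    vibration_sd: float | None = None       # default: 0.15 x amplitude (active)
    noise_sd: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.regime not in REGIMES:
            raise ValueError(f"regime must be one of {REGIMES}")
        if self.duration_s <= 0 or self.rate_hz <= 0 or self.channels < 1:
            raise ValueError("invalid synthetic configuration")

    @property
    def effective_noise_sd(self) -> float:
        if self.noise_sd is not None:
            return self.noise_sd
        return 10.0 if self.regime == "active" else 3.0

    @property
    def effective_vibration_sd(self) -> float:
        # motion-coupled broadband floor; absent at rest
        if self.vibration_sd is not None:
            return self.vibration_sd
        return 0.15 * self.amplitude if self.regime == "active" else 0.0

    @property
    def effective_impact_amplitude(self) -> float:
        # heel-strike peaks in walking accelerometry are typically a small
        # multiple (2-5x) of the smooth stride oscillation
        return 2.0 * self.amplitude if self.impact_amplitude is None else self.impact_amplitude

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.rate_hz))


def _strike_times(config: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    """One heel strike per stride, with a random phase and ±1 sample jitter."""
    period = config.rate_hz / config.stride_hz
    first = rng.uniform(0.0, period)
    times = np.arange(first, config.n_samples, period)
    times += rng.integers(-1, 2, times.size)
    return times[(times >= 0) & (times < config.n_samples)].astype(np.int64)


def generate_channel(
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
    label: str = "",
    strike_times: np.ndarray | None = None,
) -> SignalChannel:
    """Generate one channel; identical (config, rng state) gives identical bytes.

    ``strike_times`` lets co-located channels share one set of heel-strike
    instants (as physical impacts do); standalone calls draw their own.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_samples
    t = np.arange(n) / config.rate_hz
    if config.regime == "active":
        values = np.zeros(n)
        for h in range(1, config.harmonics + 1):
            phase = rng.uniform(0.0, 2.0 * np.pi)
            values += (config.amplitude / h) * np.sin(
                2.0 * np.pi * h * config.stride_hz * t + phase
            )
        if strike_times is None:
            strike_times = _strike_times(config, rng)
        # sharp impact transient: full amplitude at the strike sample,
        # geometric decay over the next two samples, per-channel polarity/scale
        scale = config.effective_impact_amplitude * rng.uniform(0.5, 1.5)
        sign = rng.choice([-1.0, 1.0])
        for k in strike_times:
            for lag in range(3):
                if k + lag < n:
                    values[k + lag] += sign * scale * config.impact_decay**lag
        if config.effective_vibration_sd > 0:
            values += rng.normal(0.0, config.effective_vibration_sd, n)
        values += rng.normal(0.0, config.effective_noise_sd, n)
    else:
        offset = rng.uniform(-0.25, 0.25) * config.amplitude
        values = offset + rng.normal(0.0, config.effective_noise_sd, n)
    quantized = np.rint(values)
    clipped = np.clip(quantized, INT16_MIN, INT16_MAX)
    n_clipped = int(np.count_nonzero(clipped != quantized))
    if n_clipped:
        import warnings

        warnings.warn(f"{n_clipped} samples clipped to the int16 range", stacklevel=2)
    return SignalChannel(clipped.astype(np.int64), rate_hz=config.rate_hz, label=label)


def generate_case(config: SyntheticConfig) -> list[SignalChannel]:
    """Six (by default) co-located channels sharing one RNG stream."""
    rng = np.random.default_rng(config.seed)
    labels = [f"{axis}{i // 3 + 1}" for i, axis in enumerate(
        itertools.islice(itertools.cycle("xyz"), config.channels)
    )]
    strikes = _strike_times(config, rng) if config.regime == "active" else None
    return [
        generate_channel(config, rng, label=lab, strike_times=strikes)
        for lab in labels
    ]


def generate_corpus(
    n_cases: int,
    stationary_fraction: float = 0.5,
    seed: int = 0,
    duration_s: float = 10.0,
    base_config: SyntheticConfig | None = None,
) -> list[TestCase]:
    """A labeled, reproducible corpus for the evaluation harness.

    Cases are tagged like a gait-database corpus — subject, activity
    (the regime), trial, body segment — cycling through six lower-body
    segments. The first round(n_cases * stationary_fraction) cases are
    stationary, the rest active; per-case seeds are derived from ``seed``.
    """
    if n_cases < 1:
        raise ValueError("need at least one case")
    if not (0.0 <= stationary_fraction <= 1.0):
        raise ValueError("stationary_fraction must be in [0, 1]")
    base = base_config or SyntheticConfig(duration_s=duration_s)
    n_stationary = int(round(n_cases * stationary_fraction))
    cases = []
    for idx in range(n_cases):
        regime = "stationary" if idx < n_stationary else "active"
        config = replace(
            base,
            regime=regime,
            duration_s=duration_s,
            seed=(seed * 100003 + idx) % (2**31),
        )
        cases.append(
            TestCase(
                subject=f"S{idx // len(SEGMENTS):02d}",
                activity=regime,
                trial=idx,
                segment=SEGMENTS[idx % len(SEGMENTS)],
                channels=generate_case(config),
            )
        )
    return cases
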