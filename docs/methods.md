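# Methods

This note documents the models, numerical conventions, and design
decisions of `imucodec`: what is computed, under which assumptions, and
which defaults were chosen where the design was genuinely open.

## Signal model and predictors

A channel is a sequence of 16-bit signed samples at a fixed rate
(60 Hz is the default, matching consumer gait-capture hardware). All
codecs are causal, zero-filter-delay autoregressive linear predictors:
the prediction for sample n uses samples n−1..n−p only, so a decoder
that has reproduced the past can reproduce the prediction.

**Polynomial extrapolation.** A degree-d polynomial is least-squares
fitted to the previous p samples at positions −1..−p and evaluated at
position 0. Because the positions never change, the fit-and-evaluate
pipeline collapses to a fixed row vector e_d(CᵀC)⁻¹Cᵀ with
C[i−1, j] = (−i)^j: an order-p linear filter. Position indexing is
most-recent-first everywhere (the weight of x[n−1] comes first); this
convention reproduces the classical two-tap linear extrapolator
(2, −1). For the exact-fit case p = d+1 the weights are the alternating
binomial coefficients of forward finite-difference extrapolation —
small integers, exactly representable in fixed point. That exact fit is
the default p for every polynomial method; overdetermined histories
(p > d+1) are supported and derived by solving the normal equations.
Exact-fit filters annihilate any integer polynomial signal of degree
≤ d; all filters reproduce constants.

**Spline extrapolation.** The natural cubic spline (zero second
derivative at both end knots) through the p most recent samples,
extrapolated one step using its last cubic piece. The spline is linear
in the data, so the extrapolation is again a p-tap filter, derived by
passing unit impulses through the spline construction. A noteworthy
consequence of the natural boundary condition: the one-step
extrapolation of the last piece equals 2y_last − y_prev + M_last where
M_last is the end-knot second derivative, which the natural condition
sets to zero — so the spline extrapolator's weights are exactly
(2, −1, 0, …, 0) for every p. The method is retained as a distinct
codec (it carries a different history length and hence container
layout), and its empirical behaviour — statistically indistinguishable
from linear extrapolation apart from warm-up overhead — is consistent
with that identity. Default p is 5 (configurable 3–16).

## Fixed-point evaluation

Filter weights are quantized to Q16.16 (32-bit signed, 16 fractional
bits), rounding half away from zero so positive and negative weights
are treated symmetrically; the quantization error per weight is at most
2⁻¹⁷. Prediction is an exact 64-bit integer multiply-accumulate
followed by an arithmetic right shift of 16 — truncation toward −∞.
One fixed rounding convention is required for the encoder and decoder
to agree; floor is the cheapest and matches two's-complement shift
semantics. Histories are capped at 64 taps so the accumulator cannot
overflow. After quantization the raw weights of every derived predictor
are renormalized to sum to exactly 2¹⁶ (the correction, a few raw
ticks, is folded into the most-recent weight): without this, a
predictor whose real weights sum to 1 can still leave nonzero residuals
on large constant inputs, breaking the constants-are-free property.

Integer-valued weights (delta, exact-fit polynomials, the spline
filter) incur no rounding at all, so those predictors are exact integer
arithmetic end to end.

## Residual coding

Residuals are mapped to unsigned integers by zigzag interleaving
(0, −1, 1, −2, … → 0, 1, 2, 3, …), which preserves magnitude ordering —
small residuals of either sign get short codes, matching the two-sided
geometric shape of predictor residuals. Rice coding at order m emits
the quotient u >> m in unary (q ones, one zero) and the remainder in m
bits: exactly m + ⌊u/2ᵐ⌋ + 1 bits per value. The per-channel, per-block
order is chosen by exhaustive search over m ∈ [0, 15], minimizing the
closed-form total; ties break toward smaller m. (A one-pass heuristic,
m = ⌊log₂ max(1, mean u)⌋, is available behind a flag; the exhaustive
two-pass search is the default since the evaluation setting is
offline.) A codeword whose quotient exceeds 47 escapes to 48 one-bits
plus the raw value in 32 bits, bounding the damage of any single
adversarial sample at 80 bits.

## Container and baselines

The `.kc` container stores a 16-byte fixed header (magic "KC01",
version, method id, d, p, channel count s, sample count l), explicit
Q16.16 coefficients when the predictor is a custom fitted model, and
per channel: the Rice order, the first min(p, l) samples verbatim as
warm-up (the decoder needs history; for signals shorter than p the
whole signal is warm-up), the payload byte count, and the zero-padded
MSB-first bitstream. Channels are compressed independently. Everything
needed to decode is in the file.

Compression ratios are computed against a constant-width CSV dialect:
every value rendered as an explicit sign plus five zero-padded digits,
comma-separated, newline-terminated — 7 bytes per value, so the
baseline size depends only on the data's shape. This makes the raw
binary baseline (two bytes per sample) sit at CR 3.5 regardless of
content, a useful anchor when comparing absolute ratios; absolute CRs
scale linearly with the bytes-per-value of whatever text dialect a
deployment actually uses. The DEFLATE baseline compresses the CSV bytes
at level 6.

## Optimal reference models

The a-posteriori optimal linear predictor minimizes
‖x − Xa‖₁ + λ‖a‖₁. The L1 residual norm is the principled objective
because the relaxed Rice-coded size of a residual block is affine in
Σ|e|: l(m+1) + 2⁻ᵐ Σ|e| after dropping the quotient floor. The λ
penalty (default 0; grid {0, 0.1, 1, 10} in the CLI's reach) encourages
sparse models, which quantize with less error. The program is solved
exactly as a linear program with auxiliary variables for both
absolute-value terms, using HiGHS with feasibility tolerances pinned at
1e−8 for determinism. The AR variant fits each stream from its own
past (default order 8 for corpus experiments; smaller orders in the
shipped tests to keep runtimes in seconds); MVAR stacks the lagged past
of all s co-located streams. AR is always feasible for MVAR, so the
MVAR objective can never exceed the summed AR objectives by more than
solver tolerance — an invariant the tests assert. Both fits are
non-causal references; `quantize_model` converts an AR fit to a Q16.16
predictor the container codec can actually run (MVAR is evaluated
offline only — a cross-stream fixed-point codec is deliberately out of
scope).

On a random walk with symmetric continuous increments, delta coding is
the L1-optimal autoregressive predictor; the fitted optimum beats it
only through finite-sample overfitting (measured ≲ 0.2% at n = 1500).
With binary ±1 increments the optimum is non-unique — (2, −1, 0, …)
attains the same expected cost — so tests use Gaussian-increment walks
where the identification is clean.

## Synthetic corpus

The generator emulates the statistical shape of lower-body gait
recordings in two regimes, six co-located channels, 60 Hz, 16-bit:

* **stationary** (sitting/standing): constant orientation offset plus
  Gaussian sensor noise, default sd 3 LSB.
* **active** (walking/running/biking): the sum of
  1. a harmonic series at the stride frequency — default 1.8 Hz,
     4 harmonics, amplitude 8000 LSB with 1/h roll-off, random phases —
     the smooth limb oscillation;
  2. one heel-strike transient per stride: a sharp spike decaying
     geometrically (factor 0.35) over three samples, timed identically
     across the co-located channels with per-channel polarity and
     scale. Default peak 2× the smooth amplitude: impact peaks in
     walking accelerometry are typically a small multiple (2–5×) of
     the smooth oscillation;
  3. a broadband vibration floor, Gaussian with sd 0.15× amplitude:
     soft-tissue oscillation and unresolved high-frequency dynamics
     that scale with movement intensity;
  4. Gaussian sensor noise, default sd 10 LSB.

The broadband terms (2, 3) are essential, not decoration. A purely
harmonic 1.8 Hz series is band-limited far below the 10 Hz frequency
(f_s/6) above which differencing amplifies rather than attenuates, so
every added difference order would *reduce* its residuals and
high-order extrapolators would dominate — the opposite of how real
movement data behaves. Real gait signals are spectrally flat at high
frequencies precisely because of impacts and vibration; with these
components at their defaults the generator reproduces the structure
real corpora show: delta coding ranks first essentially always, each
added polynomial order ranks strictly worse, and stationary cases
compress roughly 3× more than active ones (measured ≈ 12.7 vs ≈ 4.0
here).

What the generator does **not** emulate: gravity bias and orientation
drift, inter-segment biomechanical coupling, activity transitions
within a recording, sensor saturation patterns, or any particular
hardware's noise spectrum. Passing tests on synthetic corpora therefore
demonstrate the codec machinery and the *qualitative* performance
structure, not the absolute compression ratios of any real corpus;
absolute ratios also scale with the CSV dialect width. Samples
exceeding the int16 range are clipped with a warning counter.

Corpora are labeled (subject, activity, trial, body segment) to mirror
gait-database granularity; per-case seeds derive deterministically from
the corpus seed, and identical seeds give byte-identical corpora.

## Evaluation harness

Per test case and method the harness records CSV bytes, compressed
bytes, and their ratio. The per-method aggregate reported first is the
unweighted mean of per-case CRs; the pooled byte ratio is reported
alongside (the two differ when case sizes or difficulty vary). Methods
are compared with the Friedman rank test — per-case ranks, 1 = highest
CR, average ranks on ties — using the classical statistic
χ²_F = 12/(Nk(k+1)) ΣR_j² − 3N(k+1) against χ² with k−1 degrees of
freedom, followed on rejection by the Nemenyi critical difference
CD = q_{α,k} √(k(k+1)/6N) with the α = 0.05 critical values embedded
for k ≤ 10 (they match the studentized range at infinite df divided by
√2). Data classes (activities) are compared for the best-ranked method
with one-way ANOVA and Tukey's HSD, both at α = 0.05 — appropriate
because per-class CR distributions are near normal even though the
pooled distribution is bimodal. Single-case corpora skip the statistics
with a warning; per-case codec failures are recorded, never fatal.

## Problem sizes and tolerances

Shipped tests and the acceptance script run entirely on generated data
at sizes chosen to keep the full suite in the tens of seconds while
leaving the measured effects far from their decision thresholds:
24-case corpora of 8-second, six-channel cases for the benchmark
statistics; 300–1000 randomized signals for round-trip sweeps; n = 1500
(AR) and n = 400 × 6 streams (MVAR) for the LP fits. Solver tolerances
are 1e−8; coefficient-derivation checks are at 1e−9 against exact
rational oracles; everything downstream of quantization is exact
integer arithmetic and asserted bit-for-bit.

## Known limitations

* Rice orders are static per channel block; no adaptive order tracking
  or dropped-packet resynchronization (the container is a file format,
  not a transport framing).
* No cross-channel prediction in the shipped codecs — the MVAR results
  here and elsewhere suggest linear cross-axis structure is weak
  anyway; nonlinear models are untouched.
* The natural-spline codec is mathematically a re-parameterized linear
  extrapolator (see above); other boundary conditions (not-a-knot,
  clamped) would give a genuinely distinct method but are not part of
  the shipped set.
* Bit-exact compatibility with other fixed-point implementations is
  not promised — the rounding conventions here (floor accumulator,
  half-away coefficient rounding, sum renormalization) are
  self-consistent but one choice among several.
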