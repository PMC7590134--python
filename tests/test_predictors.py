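"""Predictor derivation, the encode/decode contract, and losslessness."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from imucodec.fixedpoint import ONE_RAW
from imucodec.predictors import (
    CorruptStreamError,
    METHOD_NAMES,
    PredictorSpec,
    ResidualStream,
    SignalChannel,
    delta_spec,
    derive_poly_coeffs,
    derive_spline_coeffs,
    poly_spec,
    predict_decode,
    predict_encode,
    predictor_from_name,
    spline_spec,
)

from ._oracles import poly_weights_rational, spline_one_step_oracle


class TestPolyCoefficients:
    def test_printed_linear_extrapolator(self):
        assert derive_poly_coeffs(1, 2).tolist() == [2.0, -1.0]

    @pytest.mark.parametrize("d", range(6))
    def test_exact_fit_weights_are_alternating_binomials(self, d):
        weights = derive_poly_coeffs(d, d + 1)
        oracle = poly_weights_rational(d, d + 1)
        assert all(w == int(w) for w in weights)
        assert [int(w) for w in weights] == [int(f) for f in oracle]
        assert sum(weights) == 1

    @pytest.mark.parametrize("d, p", [(1, 4), (2, 5), (3, 5), (3, 8), (5, 12)])
    def test_overdetermined_weights_match_rational_least_squares(self, d, p):
        weights = derive_poly_coeffs(d, p)
        oracle = np.array([float(f) for f in poly_weights_rational(d, p)])
        np.testing.assert_allclose(weights, oracle, atol=1e-9)
        assert abs(weights.sum() - 1.0) < 1e-9

    def test_invalid_orders_rejected(self):
        with pytest.raises(ValueError):
            derive_poly_coeffs(2, 2)
        with pytest.raises(ValueError):
            derive_poly_coeffs(-1, 1)


class TestSplineCoefficients:
    @pytest.mark.parametrize("p", [3, 4, 5, 8, 12])
    def test_impulse_weights_match_tridiagonal_oracle(self, p):
        weights = derive_spline_coeffs(p)
        for j in range(p):            # impulse at knot j, most recent is p-1
            impulse = np.zeros(p)
            impulse[j] = 1.0
            assert weights[p - 1 - j] == pytest.approx(
                spline_one_step_oracle(impulse), abs=1e-9
            )

    @pytest.mark.parametrize("p", [3, 5, 9])
    def test_reproduces_constants_and_ramps(self, p):
        weights = derive_spline_coeffs(p)
        assert weights.sum() == pytest.approx(1.0, abs=1e-9)
        # ramp 1..p (oldest->newest): weights applied most-recent-first
        ramp = np.arange(p, 0, -1, dtype=float)
        assert weights @ ramp == pytest.approx(p + 1, abs=1e-9)

    def test_natural_boundary_collapses_to_linear_extrapolation(self):
        """With zero curvature enforced at the last knot, the one-step
        extrapolation of the last cubic piece is exactly 2 x[n-1] - x[n-2]."""
        for p in (3, 4, 7):
            weights = derive_spline_coeffs(p)
            expected = np.zeros(p)
            expected[:2] = [2.0, -1.0]
            np.testing.assert_allclose(weights, expected, atol=1e-9)

    def test_too_few_knots_rejected(self):
        with pytest.raises(ValueError):
            derive_spline_coeffs(2)


class TestEncodeDecode:
    @pytest.mark.parametrize(
        "samples, method, warmup, residuals",
        [
            ([5, 5, 5, 5], "delta", [5], [0, 0, 0]),
            ([1, 3, 6], "delta", [1], [2, 3]),
            ([1, 2, 3, 4, 5], "linear", [1, 2], [0, 0, 0]),
        ],
    )
    def test_encode_examples(self, samples, method, warmup, residuals):
        stream = predict_encode(
            SignalChannel(np.array(samples)), predictor_from_name(method)
        )
        assert stream.warmup.tolist() == warmup
        assert stream.residuals.tolist() == residuals

    def test_decode_example(self):
        stream = ResidualStream(np.array([1, 2]), np.array([0, 0]), 2)
        out = predict_decode(stream, predictor_from_name("linear"))
        assert out.samples.tolist() == [1, 2, 3, 4]

    def test_short_signal_stored_entirely_as_warmup(self):
        spec = spline_spec(5)
        channel = SignalChannel(np.array([7, -3, 2]))
        stream = predict_encode(channel, spec)
        assert stream.warmup.tolist() == [7, -3, 2]
        assert stream.residuals.size == 0
        assert predict_decode(stream, spec).samples.tolist() == [7, -3, 2]

    @pytest.mark.parametrize("method", METHOD_NAMES)
    def test_exact_on_matching_polynomial_signals(self, method):
        """The exact-fit order-d predictor has all-zero residuals on any
        integer polynomial signal of degree <= d (spline: degree <= 1)."""
        spec = predictor_from_name(method)
        d = 1 if method == "spline" else spec.d
        if d == 0:
            signal = np.full(30, -417)
        else:
            # widest integer range keeping n^d plus a linear term in int16
            bound = min(20, int((32000 / 2) ** (1.0 / d)))
            n = np.arange(-bound, bound + 1)
            signal = n**d + 3 * n
        assert signal.size > spec.p
        stream = predict_encode(SignalChannel(signal), spec)
        assert not stream.residuals.any()

    @pytest.mark.parametrize("method", METHOD_NAMES)
    @pytest.mark.parametrize("value", [-32768, -1, 0, 17, 32767])
    def test_constant_reproduction_after_warmup(self, method, value):
        spec = predictor_from_name(method)
        channel = SignalChannel(np.full(40, value))
        stream = predict_encode(channel, spec)
        assert not stream.residuals.any()

    def test_decode_flags_out_of_range_reconstruction(self):
        stream = ResidualStream(np.array([32000]), np.array([2000]), 1)
        with pytest.raises(CorruptStreamError):
            predict_decode(stream, delta_spec())


@settings(derandomize=True, max_examples=40)
@given(
    samples=st.lists(
        st.integers(min_value=-32768, max_value=32767), min_size=1, max_size=120
    ),
    method=st.sampled_from(METHOD_NAMES),
)
def test_round_trip_is_identity_for_every_method(samples, method):
    spec = predictor_from_name(method)
    channel = SignalChannel(np.array(samples))
    decoded = predict_decode(predict_encode(channel, spec), spec)
    assert decoded.samples.tolist() == samples


def test_spec_invariants_enforced():
    with pytest.raises(ValueError):
        PredictorSpec("delta", 0, 2, delta_spec().coeffs * 2)
    with pytest.raises(ValueError):
        PredictorSpec("nonsense", 0, 1, delta_spec().coeffs)
    assert poly_spec(0, 1) == delta_spec()


def test_quantized_coefficients_sum_to_exactly_one():
    for spec in (poly_spec(3, 6), spline_spec(5), poly_spec(5)):
        assert sum(c.raw for c in spec.coeffs) == ONE_RAW
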