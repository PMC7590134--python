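"""A-posteriori optimal linear predictive models.

The shipped codecs use fixed filters; these routines instead fit, with
full knowledge of the signal, the autoregressive coefficients that
minimize the total absolute residual

    minimize_a  ||x - X a||_1  +  lambda * ||a||_1

The L1 residual norm is the right objective because the Rice-coded size
of a residual block is, up to the rounding in the quotient, an affine
function of sum|e[n]| (about l*(m+1) + 2^-m * sum|e|); the optional L1
coefficient penalty encourages sparse models, which quantize to Q16.16
with less error. The fit is non-causal and therefore a reference bound,
not a deployable codec.

AR fits each stream from its own past; MVAR predicts each stream from
the past of all s co-located streams (s*p regressors per target), which
bounds whatever linear cross-axis redundancy exists.

The convex program is solved exactly as a linear program (auxiliary
variables for both absolute-value terms) with the HiGHS solver.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.optimize import linprog

from .fixedpoint import quantize_vector
from .predictors import PredictorSpec, SignalChannel, custom_spec

#: dual feasibility / optimality tolerance passed to HiGHS; pinned so that
#: repeated fits of the same data are bit-identical
SOLVER_TOLERANCE = 1e-8


class SolverError(RuntimeError):
    """The LP solver did not converge to an optimum."""


@dataclass(frozen=True)
class OptimalModel:
    """Fitted reference model.

    ``coefficients`` has shape (p,) for AR and (s, s, p) for MVAR, where
    entry [i, j, k] weights stream j, lag k+1, in the prediction of
    stream i. ``objective`` is the achieved LP objective (residual norm
    plus penalty); ``total_abs_residual`` is sum|e| alone.
    """

    kind: str
    p: int
    lam: float
    coefficients: np.ndarray
    objective: float
    total_abs_residual: float
    n_obs: int


def _lagged_design(samples: np.ndarray, p: int) -> tuple[np.ndarray, np.ndarray]:
    """Target y[n] = x[n] and design rows [x[n-1], ..., x[n-p]], n = p..l-1."""
    x = np.asarray(samples, dtype=float)
    n = x.size - p
    X = np.empty((n, p))
    for k in range(p):
        X[:, k] = x[p - 1 - k : p - 1 - k + n]
    return x[p:], X


def _solve_l1(y: np.ndarray, X: np.ndarray, lam: float) -> tuple[np.ndarray, float]:
    """min ||y - X a||_1 + lam ||a||_1 as an LP over (a, u, v).

    u bounds the residual magnitudes, v the coefficient magnitudes:
        X a - u <= y,  -X a - u <= -y,  a - v <= 0,  -a - v <= 0.
    """
    n, k = X.shape
    Xs = sp.csr_matrix(X)
    In = sp.identity(n, format="csr")
    Ik = sp.identity(k, format="csr")
    Zn = sp.csr_matrix((n, k))
    Zk = sp.csr_matrix((k, n))
    A = sp.vstack(
        [
            sp.hstack([Xs, -In, Zn]),
            sp.hstack([-Xs, -In, Zn]),
            sp.hstack([Ik, Zk, -Ik]),
            sp.hstack([-Ik, Zk, -Ik]),
        ],
        format="csr",
    )
    b = np.concatenate([y, -y, np.zeros(2 * k)])
    cost = np.concatenate([np.zeros(k), np.ones(n), np.full(k, lam)])
    bounds = [(None, None)] * k + [(0, None)] * (n + k)
    res = linprog(
        cost,
        A_ub=A,
        b_ub=b,
        bounds=bounds,
        method="highs",
        options={
            "primal_feasibility_tolerance": SOLVER_TOLERANCE,
            "dual_feasibility_tolerance": SOLVER_TOLERANCE,
        },
    )
    if not res.success:
        raise SolverError(f"L1 fit failed: {res.message}")
    return res.x[:k], float(res.fun)


def fit_l1_ar(channel: SignalChannel, p: int = 8, lam: float = 0.0) -> OptimalModel:
    """Fit the L1-optimal order-``p`` AR model to one channel."""
    if lam < 0:
        raise ValueError("penalty weight must be non-negative")
    if len(channel) < p + 10:
        raise ValueError("signal too short to identify an order-p model")
    y, X = _lagged_design(channel.samples, p)
    a, objective = _solve_l1(y, X, lam)
    residual = float(np.abs(y - X @ a).sum())
    return OptimalModel("AR", p, lam, a, objective, residual, y.size)


def fit_l1_mvar(
    channels: list[SignalChannel], p: int = 8, lam: float = 0.0
) -> OptimalModel:
    """Fit the L1-optimal multivariate AR model over co-located streams.

    One LP per target stream; the design stacks the lagged past of every
    stream (s*p columns). The AR solution is always feasible here, so in
    exact arithmetic the MVAR objective can never exceed the summed AR
    objectives.
    """
    if lam < 0:
        raise ValueError("penalty weight must be non-negative")
    s = len(channels)
    if s < 2:
        raise ValueError("MVAR needs at least two streams")
    lengths = {len(c) for c in channels}
    if len(lengths) != 1:
        raise ValueError("channels must have equal lengths")
    if min(lengths) < s * p + 10:
        raise ValueError("signal too short for the expanded design")
    designs = [_lagged_design(c.samples, p) for c in channels]
    X_full = np.hstack([X for _, X in designs])          # columns: stream j, lags 1..p
    coeffs = np.empty((s, s, p))
    objective = 0.0
    residual = 0.0
    n_obs = 0
    for i, (y, _) in enumerate(designs):
        a, obj = _solve_l1(y, X_full, lam)
        coeffs[i] = a.reshape(s, p)
        objective += obj
        residual += float(np.abs(y - X_full @ a).sum())
        n_obs += y.size
    return OptimalModel("MVAR", p, lam, coeffs, objective, residual, n_obs)


def delta_l1_objective(channel: SignalChannel, p: int) -> float:
    """sum|e| of plain delta coding over the same rows an order-``p`` fit
    uses — the feasible point (1, 0, ..., 0) of the L1 program."""
    x = np.asarray(channel.samples, dtype=float)
    return float(np.abs(np.diff(x)[p - 1 :]).sum())


def approx_encoded_size(residuals: np.ndarray, m: int, l: int | None = None) -> float:
    """Relaxed Rice-coded size, in bits: l + l*m + 2^-m * sum|e|.

    This is the affine surrogate the L1 objective descends, obtained by
    dropping the floor in the quotient; it is not the exact bitstream
    length (the exact length also pays for the zigzag interleave and the
    rounding, which together stay within about one bit per sample for a
    well-chosen m).
    """
    if m < 0:
        raise ValueError("Rice order must be non-negative")
    residuals = np.asarray(residuals)
    if l is None:
        l = residuals.size
    return float(l + l * m + (2.0 ** -m) * np.abs(residuals).sum())


def quantize_model(model: OptimalModel) -> PredictorSpec:
    """Quantize a fitted AR model to a Q16.16 predictor usable by the codec.

    MVAR models are evaluated offline in real arithmetic only (a
    cross-stream fixed-point codec is deliberately not shipped).
    Raises on coefficients outside the Q16.16 range.
    """
    if model.kind != "AR":
        raise ValueError("only AR models can be quantized to a codec predictor")
    if np.abs(model.coefficients).max() >= 32768:
        raise OverflowError("coefficient magnitude exceeds the Q16.16 range")
    return custom_spec(quantize_vector(model.coefficients))
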