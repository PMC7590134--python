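"""Independent reference computations used to freeze expected values.

Everything here is deliberately implemented from first principles
(exact rational arithmetic, textbook tridiagonal spline equations,
brute-force enumeration) and never calls into the package under test.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np


def solve_rational(A: list[list[Fraction]], B: list[list[Fraction]]):
    """Exact Gaussian elimination with partial pivoting over Fractions.

    Solves A X = B for a square A; B holds one right-hand side per column.
    """
    n = len(A)
    m = len(B[0])
    M = [row_a[:] + row_b[:] for row_a, row_b in zip(A, B)]
    for col in range(n):
        pivot = max(range(col, n), key=lambda r: abs(M[r][col]))
        if M[pivot][col] == 0:
            raise ZeroDivisionError("singular system")
        M[col], M[pivot] = M[pivot], M[col]
        inv = Fraction(1, 1) / M[col][col]
        M[col] = [v * inv for v in M[col]]
        for r in range(n):
            if r != col and M[r][col] != 0:
                factor = M[r][col]
                M[r] = [v - factor * w for v, w in zip(M[r], M[col])]
    return [row[n : n + m] for row in M]


def poly_weights_rational(d: int, p: int) -> list[Fraction]:
    """One-step polynomial-extrapolation weights by exact least squares.

    Fit sum_j b_j t^j to the samples at t = -1..-p, evaluate at t = 0:
    the weight of x[n-i] is row 0 of (C^T C)^{-1} C^T with C[i-1, j] =
    (-i)^j. Exact rational arithmetic throughout.
    """
    C = [[Fraction(-i) ** j for j in range(d + 1)] for i in range(1, p + 1)]
    G = [
        [sum(C[r][i] * C[r][j] for r in range(p)) for j in range(d + 1)]
        for i in range(d + 1)
    ]
    Ct = [[C[r][i] for r in range(p)] for i in range(d + 1)]
    W = solve_rational(G, Ct)
    return W[0]


def spline_one_step_oracle(y: np.ndarray) -> float:
    """Natural-cubic-spline prediction one step past the last of p knots.

    Solves the textbook tridiagonal system for the knot second
    derivatives M (M[0] = M[p-1] = 0; unit spacing):

        M[i-1] + 4 M[i] + M[i+1] = 6 (y[i-1] - 2 y[i] + y[i+1])

    then evaluates the last cubic piece, written in the standard
    second-derivative form, at one unit past the final knot.
    """
    y = np.asarray(y, dtype=float)
    p = y.size
    assert p >= 3
    M = np.zeros(p)
    interior = p - 2
    A = np.zeros((interior, interior))
    rhs = np.zeros(interior)
    for row, i in enumerate(range(1, p - 1)):
        A[row, row] = 4.0
        if row > 0:
            A[row, row - 1] = 1.0
        if row < interior - 1:
            A[row, row + 1] = 1.0
        rhs[row] = 6.0 * (y[i - 1] - 2.0 * y[i] + y[i + 1])
    M[1 : p - 1] = np.linalg.solve(A, rhs)
    a, b = p - 2, p - 1          # last interval [a, b], evaluate at t = b + 1
    t = float(p)
    return (
        M[a] * (b - t) ** 3 / 6.0
        + M[b] * (t - a) ** 3 / 6.0
        + (y[a] - M[a] / 6.0) * (b - t)
        + (y[b] - M[b] / 6.0) * (t - a)
    )


def rice_bits_oracle(u: int, m: int) -> int:
    """Codeword size by direct construction: unary quotient + m-bit remainder."""
    q = u >> m
    return len("1" * q + "0") + m
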