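"""Independent brute-force oracles used to check the estimator.

Everything here is a literal translation of the defining formulas, kept free
of the package's own linear-algebra shortcuts: the least-squares solution via
explicit normal equations with a hand-rolled cofactor 4x4 inverse, the HAC
sandwich as a double loop over time and lag, and the Student-t survival
function by numerical integration of its density.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.integrate import quad


def inverse_4x4(a):
    """Cofactor-expansion inverse of a 4x4 matrix (no numpy.linalg)."""
    a = [[float(a[i][j]) for j in range(4)] for i in range(4)]

    def det3(m):
        return (
            m[0][0] * (m[1][1] * m[2][2] - m[1][2] * m[2][1])
            - m[0][1] * (m[1][0] * m[2][2] - m[1][2] * m[2][0])
            + m[0][2] * (m[1][0] * m[2][1] - m[1][1] * m[2][0])
        )

    def minor(m, i, j):
        return [[m[r][c] for c in range(4) if c != j] for r in range(4) if r != i]

    cof = [[(-1) ** (i + j) * det3(minor(a, i, j)) for j in range(4)] for i in range(4)]
    det = sum(a[0][j] * cof[0][j] for j in range(4))
    return np.array([[cof[j][i] / det for j in range(4)] for i in range(4)])


def ols_normal_equations(design: np.ndarray, y: np.ndarray) -> np.ndarray:
    """(D'D)^-1 D'y computed with the hand-rolled inverse."""
    dtd = design.T @ design
    return inverse_4x4(dtd) @ (design.T @ y)


def hac_double_loop(
    design: np.ndarray,
    resid: np.ndarray,
    lag: int,
    small_sample: bool = False,
) -> np.ndarray:
    """Bartlett-kernel HAC sandwich, written as literal nested loops."""
    n, k = design.shape
    meat = np.zeros((k, k))
    for t in range(n):
        xt = design[t]
        meat += resid[t] ** 2 * np.outer(xt, xt)
    for j in range(1, lag + 1):
        w = 1.0 - j / (lag + 1.0)
        for t in range(j, n):
            xt, xs = design[t], design[t - j]
            meat += w * resid[t] * resid[t - j] * (
                np.outer(xt, xs) + np.outer(xs, xt)
            )
    bread = inverse_4x4(design.T @ design)
    cov = bread @ meat @ bread
    if small_sample:
        cov = cov * (n / (n - k))
    return cov


def t_sf_by_quadrature(x: float, df: int) -> float:
    """P(T > x) for Student-t with df dof, integrating the density."""
    const = math.gamma((df + 1) / 2.0) / (
        math.sqrt(df * math.pi) * math.gamma(df / 2.0)
    )

    def pdf(u):
        return const * (1.0 + u * u / df) ** (-(df + 1) / 2.0)

    value, _ = quad(pdf, x, np.inf)
    return value


def normal_sf_by_erfc(x: float) -> float:
    """P(Z > x) via the complementary error function identity."""
    return 0.5 * math.erfc(x / math.sqrt(2.0))
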