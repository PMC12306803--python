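"""Penalized B-spline basis for functional coefficients.

Each functional coefficient beta_r(s) is expanded in m B-spline basis
functions, beta_r(s) = sum_d theta_{r,d} B_d(s), and regularized with a
difference penalty on the spline coefficients. With q covariates plus an
intercept the stacked coefficient vector theta has length p = m(q+1) and the
penalty matrix S is block diagonal with D_d^T D_d in each m x m block, where
D_d is the d-th order difference matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline

__all__ = ["BasisSystem", "build_basis", "design_row", "coef_curves", "expand_lambda"]


def difference_matrix(m: int, order: int) -> np.ndarray:
    """d-th order difference matrix D_d of shape (m-d, m)."""
    return np.diff(np.eye(m), n=order, axis=0)


@dataclass
class BasisSystem:
    """B-spline basis evaluated on a grid, with its difference penalty.

    Attributes
    ----------
    B : (L, m) basis evaluation matrix (rows sum to one).
    m : basis dimension.
    order : spline order (4 = cubic).
    knots : full knot vector with replicated boundary knots.
    diff_order : order of the difference penalty.
    S_block : (m, m) penalty block D_d^T D_d shared by every coefficient.
    """

    B: np.ndarray
    m: int
    order: int
    knots: np.ndarray
    diff_order: int
    S_block: np.ndarray = field(repr=False)

    @property
    def L(self) -> int:
        return self.B.shape[0]

    def penalty(self, q: int) -> np.ndarray:
        """Block-diagonal penalty S of shape (p, p), p = m(q+1)."""
        p = self.m * (q + 1)
        S = np.zeros((p, p))
        for r in range(q + 1):
            sl = slice(r * self.m, (r + 1) * self.m)
            S[sl, sl] = self.S_block
        return S


def build_basis(grid, m: int = 13, order: int = 4, diff_order: int = 2) -> BasisSystem:
    """Construct a uniform B-spline basis on a grid rescaled to [0, 1].

    Knots are uniform with ``m - order`` interior knots and replicated
    boundary knots (so ten "knots" spanning the domain inclusive of both
    boundaries corresponds to m = 13 cubic basis functions).

    Parameters
    ----------
    grid : strictly increasing grid of functional-domain points.
    m : basis dimension; requires order <= m <= len(grid).
    order : spline order (degree + 1).
    diff_order : order of the difference penalty.
    """
    grid = np.asarray(grid, dtype=float)
    L = grid.shape[0]
    if m < order:
        raise ValueError(f"m={m} must be at least the spline order {order}")
    if m > L:
        raise ValueError(f"m={m} basis functions cannot have full rank on L={L} points")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing")
    # rescale to [0,1] for conditioning; original units are kept by callers
    x = (grid - grid[0]) / (grid[-1] - grid[0])
    k = order - 1
    interior = np.linspace(0.0, 1.0, m - order + 2)[1:-1]
    knots = np.concatenate([np.zeros(order), interior, np.ones(order)])
    # design_matrix is exclusive of the right boundary; nudge x=1 inside
    xe = np.minimum(x, 1.0 - 1e-12)
    B = BSpline.design_matrix(xe, knots, k).toarray()
    D = difference_matrix(m, diff_order)
    return BasisSystem(B=B, m=m, order=order, knots=knots,
                       diff_order=diff_order, S_block=D.T @ D)


def expand_lambda(lam, m: int) -> np.ndarray:
    """Expand per-coefficient smoothing parameters to the diagonal of Lambda.

    ``lam`` has length q+1 (one value per coefficient function); the result
    has length p = m(q+1), repeating lam[r] over block r.
    """
    lam = np.asarray(lam, dtype=float)
    if np.any(lam < 0):
        raise ValueError("smoothing parameters must be non-negative")
    return np.repeat(lam, m)


def design_row(basis: BasisSystem, s_index: int, x) -> np.ndarray:
    """Design row [B(s), x_1 B(s), ..., x_q B(s)] of length p = m(q+1)."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    b = basis.B[s_index]
    return np.concatenate([b] + [xr * b for xr in x])


def coef_curves(basis: BasisSystem, theta) -> np.ndarray:
    """Evaluate all coefficient curves: returns (q+1, L) with rows B theta_r."""
    theta = np.asarray(theta, dtype=float)
    if theta.size % basis.m:
        raise ValueError(f"theta length {theta.size} is not a multiple of m={basis.m}")
    blocks = theta.reshape(-1, basis.m)
    return blocks @ basis.B.T
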