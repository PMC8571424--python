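"""Statistical moments of a square 2-D grid representation of a sequence.

A variable-length encoded sequence is laid out row-major into the smallest
square grid that holds it (side = ceil(sqrt(length)), tail zero-padded; 0
is the code of the unknown symbol X). Three families of moments up to
combined order 3 are computed from the grid:

* raw moments  G_xy = sum_l sum_n  l^x n^y beta_ln          (1-based l, n)
* central moments H_xy, the same sums about the grid centroid
  (location-invariant; all defined 0 when the grid mass G00 is 0)
* Hahn moments E_xy, projections onto products of discrete Hahn
  orthogonal polynomials over the grid support 0..N-1.

Ten (x, y) orders with x + y <= 3 are taken per family, in the fixed order
(0,0),(1,0),(2,0),(3,0),(0,1),(1,1),(2,1),(0,2),(1,2),(0,3) — 30 values per
grid. With both Hahn shape parameters set to 0 the Hahn polynomials reduce
to the discrete Chebyshev (Gram) family, which this module evaluates by its
three-term recurrence and normalizes numerically so that the basis is
orthonormal over x = 0..N-1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

#: the ten (x, y) moment orders, fixed order used everywhere downstream
MOMENT_ORDERS: tuple[tuple[int, int], ...] = (
    (0, 0), (1, 0), (2, 0), (3, 0), (0, 1),
    (1, 1), (2, 1), (0, 2), (1, 2), (0, 3),
)

MOMENT_ORDER_NAMES: tuple[str, ...] = tuple(f"{x}{y}" for x, y in MOMENT_ORDERS)


@dataclass(frozen=True)
class MomentSet:
    """The 30 moments of one grid: raw (G), central (H), Hahn (E)."""

    raw: np.ndarray
    central: np.ndarray
    hahn: np.ndarray

    def __post_init__(self) -> None:
        for arr in (self.raw, self.central, self.hahn):
            if arr.shape != (10,):
                raise ValueError("each moment family must have exactly 10 values")

    @property
    def values(self) -> np.ndarray:
        """The 30 values as raw(10) + central(10) + hahn(10)."""
        return np.concatenate([self.raw, self.central, self.hahn])


def to_square_matrix(codes: list[int] | np.ndarray) -> np.ndarray:
    """Lay codes out row-major into an N x N grid, N = ceil(sqrt(len)).

    Trailing cells are zero (the code of X).
    """
    codes = np.asarray(codes)
    if codes.size == 0:
        raise ValueError("cannot build a grid from an empty code list")
    n = math.isqrt(codes.size)
    if n * n < codes.size:
        n += 1
    grid = np.zeros(n * n, dtype=float)
    grid[: codes.size] = codes
    return grid.reshape(n, n)


def _index_powers(n: int, max_order: int = 3) -> np.ndarray:
    # rows: order 0..max_order, columns: 1-based index 1..n
    idx = np.arange(1, n + 1, dtype=float)
    return np.vstack([idx**k for k in range(max_order + 1)])


def raw_moments(grid: np.ndarray) -> np.ndarray:
    """G_xy = sum over cells of l^x * n^y * beta_ln, 1-based row l, col n."""
    grid = np.asarray(grid, dtype=float)
    _check_square(grid)
    p = _index_powers(grid.shape[0])
    # full table of order (x, y) sums: table[x, y] = l^x-weighted rows, n^y cols
    table = p @ grid @ p.T
    return np.array([table[x, y] for x, y in MOMENT_ORDERS])


def central_moments(grid: np.ndarray) -> np.ndarray:
    """Moments about the grid centroid; all 0 when total mass G00 is 0."""
    grid = np.asarray(grid, dtype=float)
    _check_square(grid)
    n = grid.shape[0]
    idx = np.arange(1, n + 1, dtype=float)
    g00 = grid.sum()
    if g00 == 0:
        return np.zeros(10)
    xbar = (idx @ grid.sum(axis=1)) / g00  # row centroid
    ybar = (idx @ grid.sum(axis=0)) / g00  # column centroid
    dl = np.vstack([(idx - xbar) ** k for k in range(4)])
    dn = np.vstack([(idx - ybar) ** k for k in range(4)])
    table = dl @ grid @ dn.T
    return np.array([table[x, y] for x, y in MOMENT_ORDERS])


def hahn_basis(order: int, n: int) -> np.ndarray:
    """Orthonormal discrete Hahn polynomial of given order over x = 0..N-1.

    Both shape parameters are 0, so these are the discrete Chebyshev (Gram)
    polynomials, built by the three-term recurrence

        (k+1) t_{k+1}(x) = (2k+1)(2x - N + 1) t_k(x) - k(N^2 - k^2) t_{k-1}(x)

    and normalized to unit Euclidean norm on the support. When order >= N
    the basis is exhausted and the zero vector is returned.
    """
    if n < 1:
        raise ValueError("grid side must be >= 1")
    if not 0 <= order <= 3:
        raise ValueError("only orders 0..3 are supported")
    if order >= n:
        return np.zeros(n)
    x = np.arange(n, dtype=float)
    t_prev = np.ones(n)
    if order == 0:
        return t_prev / np.linalg.norm(t_prev)
    t_cur = 2 * x - (n - 1)
    for k in range(1, order):
        t_next = ((2 * k + 1) * (2 * x - n + 1) * t_cur
                  - k * (n**2 - k**2) * t_prev) / (k + 1)
        t_prev, t_cur = t_cur, t_next
    return t_cur / np.linalg.norm(t_cur)


def hahn_moments(grid: np.ndarray) -> np.ndarray:
    """E_xy = sum_n sum_l beta_nl * h_x(n) * h_y(l) for the ten orders."""
    grid = np.asarray(grid, dtype=float)
    _check_square(grid)
    n = grid.shape[0]
    basis = np.vstack([hahn_basis(k, n) for k in range(4)])  # 4 x N
    table = basis @ grid @ basis.T
    return np.array([table[x, y] for x, y in MOMENT_ORDERS])


def moment_descriptor(grid: np.ndarray) -> MomentSet:
    """All 30 moments of a grid in the fixed raw + central + Hahn order."""
    return MomentSet(
        raw=raw_moments(grid),
        central=central_moments(grid),
        hahn=hahn_moments(grid),
    )


def _check_square(grid: np.ndarray) -> None:
    if grid.ndim != 2 or grid.shape[0] != grid.shape[1]:
        raise ValueError(f"grid must be square, got shape {grid.shape}")
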