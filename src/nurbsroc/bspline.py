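"""Clamped B-spline and rational (NURBS) basis functions on [0, 1].

The basis of degree ``m`` over a clamped knot vector

    T = (0, ..., 0, t_{m+1} < ... < t_{m+l-1}, 1, ..., 1)

(with 0 and 1 each repeated ``m + 1`` times and ``l - 1`` interior knots)
is evaluated by the Cox-de Boor recursion

    N_{k,0}(t) = 1 on [t_k, t_{k+1}), else 0
    N_{k,m}(t) = (t - t_k)/(t_{k+m} - t_k) N_{k,m-1}(t)
               + (t_{k+m+1} - t)/(t_{k+m+1} - t_{k+1}) N_{k+1,m-1}(t)

with the usual 0/0 = 0 convention for repeated knots.  The final
non-degenerate degree-0 interval is treated as closed at 1 so that the
partition of unity also holds at t = 1 and the curve interpolates its
last control point there.  Without interior knots the basis reduces
exactly to the Bernstein polynomials C(m,k) t^k (1-t)^(m-k).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "KnotVector",
    "build_knot_vector",
    "bspline_basis",
    "bspline_basis_matrix",
    "rational_basis",
    "rational_basis_matrix",
    "greville_abscissae",
]


@dataclass(frozen=True)
class KnotVector:
    """Clamped knot sequence of degree ``m`` with ``l - 1`` interior knots.

    ``knots`` has length ``2m + l + 1``; the number of basis functions
    (= number of control points) is ``m + l``.
    """

    degree: int
    interior: tuple
    knots: np.ndarray

    @property
    def l(self) -> int:
        return len(self.interior) + 1

    @property
    def n_basis(self) -> int:
        return self.degree + self.l


def build_knot_vector(m: int, interior=()) -> KnotVector:
    """Assemble a clamped knot vector on [0, 1].

    Parameters
    ----------
    m : int
        Spline degree, at least 1.
    interior : array_like
        Strictly increasing interior knots in the open interval (0, 1);
        may be empty (Bernstein case).
    """
    if m < 1:
        raise ValueError("degree m must be at least 1")
    interior = tuple(float(v) for v in np.atleast_1d(np.asarray(interior, dtype=float)))
    if len(interior) > 0:
        arr = np.asarray(interior)
        if np.any(arr <= 0.0) or np.any(arr >= 1.0):
            raise ValueError("interior knots must lie strictly inside (0, 1)")
        if np.any(np.diff(arr) <= 0.0):
            raise ValueError("interior knots must be strictly increasing")
    knots = np.concatenate([np.zeros(m + 1), np.asarray(interior, dtype=float), np.ones(m + 1)])
    return KnotVector(degree=m, interior=interior, knots=knots)


def bspline_basis_matrix(kv: KnotVector, t) -> np.ndarray:
    """Evaluate all ``m + l`` basis functions at each point of ``t``.

    Returns an array of shape ``(len(t), m + l)`` whose rows are
    non-negative and sum to one.
    """
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any((t_arr < 0.0) | (t_arr > 1.0)):
        raise ValueError("basis functions are defined on [0, 1]")
    knots = kv.knots
    m = kv.degree
    n0 = knots.size - 1  # number of degree-0 functions

    # index of the last non-degenerate interval [t_{m+l-1}, 1]; closed at 1
    last = m + kv.l - 1
    basis = np.zeros((t_arr.size, n0))
    for k in range(n0):
        lo, hi = knots[k], knots[k + 1]
        if hi > lo:
            if k == last:
                basis[:, k] = (t_arr >= lo) & (t_arr <= hi)
            else:
                basis[:, k] = (t_arr >= lo) & (t_arr < hi)

    # full triangle: degree j has n0 - j functions, of which the first
    # m + l survive at degree m
    for j in range(1, m + 1):
        nj = n0 - j
        new = np.zeros((t_arr.size, nj))
        for k in range(nj):
            acc = 0.0
            d1 = knots[k + j] - knots[k]
            if d1 > 0.0:
                acc = (t_arr - knots[k]) / d1 * basis[:, k]
            d2 = knots[k + j + 1] - knots[k + 1]
            if d2 > 0.0:
                acc = acc + (knots[k + j + 1] - t_arr) / d2 * basis[:, k + 1]
            new[:, k] = acc
        basis = new
    return basis


def bspline_basis(kv: KnotVector, t: float) -> np.ndarray:
    """Basis functions ``N_{k,m}(t)`` at a single point, length ``m + l``."""
    return bspline_basis_matrix(kv, t)[0]


def rational_basis_matrix(kv: KnotVector, w, t) -> np.ndarray:
    """Weighted (rational) basis ``R_{k,m}(t) = w_k N_{k,m}(t) / sum_j w_j N_{j,m}(t)``.

    Rows sum to one exactly; with equal weights this reduces to the plain
    B-spline basis.  The result is invariant to rescaling ``w`` by any
    positive constant.
    """
    w = np.asarray(w, dtype=float)
    if w.size != kv.n_basis:
        raise ValueError(f"expected {kv.n_basis} weights, got {w.size}")
    if np.any(w <= 0.0):
        raise ValueError("all weights must be strictly positive")
    basis = bspline_basis_matrix(kv, t)
    weighted = basis * w
    return weighted / weighted.sum(axis=1, keepdims=True)


def rational_basis(kv: KnotVector, w, t: float) -> np.ndarray:
    """Rational basis functions at a single point, length ``m + l``."""
    return rational_basis_matrix(kv, w, t)[0]


def greville_abscissae(kv: KnotVector) -> np.ndarray:
    """Averaged knot positions ``theta_k = (1/m) sum_{i=1..m} t_{i+k}``.

    These are the natural abscissae to attach control points to: they
    start at 0, end at 1, and satisfy the linear-precision identity
    ``sum_k theta_k N_{k,m}(t) = t``.
    """
    m = kv.degree
    return np.array([kv.knots[k + 1 : k + m + 1].mean() for k in range(kv.n_basis)])
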