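"""Empirical ROC curves from two-sample diagnostic-marker data.

A continuous diagnostic marker is measured on a healthy group
``X_1, ..., X_n1`` and a diseased group ``Y_1, ..., Y_n2``, with the
convention that larger marker values indicate disease.  Writing ``F`` and
``G`` for the two distribution functions, the ROC curve is

    ROC(t) = 1 - G(F^{-1}(1 - t)),    t in [0, 1],

the true-positive rate attainable at false-positive rate ``t``.  The
plug-in (empirical) estimator replaces ``F`` and ``G`` by the empirical
distribution functions of the two samples, which yields a right-continuous
step function jumping at the attained false-positive rates ``i / n1``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Sample",
    "EmpiricalROC",
    "ecdf_quantile",
    "empirical_roc",
    "auc",
    "flip_marker",
]


@dataclass(frozen=True)
class Sample:
    """Two independent samples of a continuous diagnostic marker.

    Parameters
    ----------
    x : array_like
        Marker values for the healthy (non-diseased) group, length ``n1``.
    y : array_like
        Marker values for the diseased group, length ``n2``.

    Larger values are assumed to indicate disease; use :func:`flip_marker`
    (or ``Sample.flip()``) for negative predictors.
    """

    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        x = np.atleast_1d(np.asarray(self.x, dtype=float))
        y = np.atleast_1d(np.asarray(self.y, dtype=float))
        if x.size == 0 or y.size == 0:
            raise ValueError("both groups must contain at least one observation")
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
            raise ValueError("marker values must be finite")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)

    @property
    def n1(self) -> int:
        return self.x.size

    @property
    def n2(self) -> int:
        return self.y.size

    def flip(self) -> "Sample":
        """Negate all marker values (for markers that decrease with disease)."""
        return Sample(-self.x, -self.y)


def ecdf_quantile(values, p: float) -> float:
    """Generalized inverse of the empirical CDF.

    Returns ``inf{x : F_n(x) >= p}`` for ``p > 0`` (the type-1 quantile,
    i.e. the ``ceil(p * n)``-th order statistic) and ``min(values)`` for
    ``p = 0``.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot take a quantile of an empty sample")
    if not np.all(np.isfinite(v)):
        raise ValueError("values must be finite")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must lie in [0, 1], got {p!r}")
    v = np.sort(v)
    if p == 0.0:
        return float(v[0])
    # small slack so that p = k/n computed in floating point lands on k
    k = int(np.ceil(p * v.size - 1e-9))
    return float(v[max(k, 1) - 1])


@dataclass(frozen=True)
class EmpiricalROC:
    """Step-function representation of the empirical ROC curve.

    ``fpr_grid`` holds the attained false-positive rates ``i / n1`` for
    ``i = 0, ..., n1``; ``roc_values[i]`` is the sensitivity attained on
    the segment ``[i/n1, (i+1)/n1)`` (the last entry, at FPR 1, is 1).

    Calling the object evaluates the curve: right-continuous on ``(0, 1)``,
    anchored at ``ROC(0) = 0`` and ``ROC(1) = 1`` like every ROC curve.

    ``fpr_points`` / ``tpr_points`` are the curve's operating points: one
    pair ``(FPR_j, TPR_j)`` per distinct pooled marker value (threshold,
    counted with >=) plus the trivial (0, 0) point, ordered by descending
    threshold.  Several points can share an FPR (vertical runs of the
    staircase); these points — not a uniform grid — are the evaluation
    points used for weight fitting, knot placement and the AIC.
    """

    fpr_grid: np.ndarray
    roc_values: np.ndarray
    n1: int
    n2: int
    fpr_points: np.ndarray
    tpr_points: np.ndarray

    @classmethod
    def from_sample(cls, sample: Sample) -> "EmpiricalROC":
        xs = np.sort(sample.x)
        ys = np.sort(sample.y)
        n1, n2 = xs.size, ys.size
        # on [i/n1, (i+1)/n1) the quantile F^{-1}(1-t) is the order statistic
        # x_(n1-i); the attained sensitivity is 1 - G_n2(x_(n1-i))
        thresholds = xs[::-1]
        g = np.searchsorted(ys, thresholds, side="right") / n2
        values = np.concatenate([1.0 - g, [1.0]])
        fpr = np.arange(n1 + 1) / n1
        # operating points: thresholds at the distinct pooled values
        pooled = np.unique(np.concatenate([xs, ys]))[::-1]
        fpr_pts = 1.0 - np.searchsorted(xs, pooled, side="left") / n1
        tpr_pts = 1.0 - np.searchsorted(ys, pooled, side="left") / n2
        fpr_pts = np.concatenate([[0.0], fpr_pts])
        tpr_pts = np.concatenate([[0.0], tpr_pts])
        return cls(fpr, values, n1, n2, fpr_pts, tpr_pts)

    @property
    def n_points(self) -> int:
        """Number of operating points on the curve."""
        return self.fpr_points.size

    def __call__(self, t):
        t_arr = np.asarray(t, dtype=float)
        if np.any((t_arr < 0.0) | (t_arr > 1.0)):
            raise ValueError("ROC curves are defined on [0, 1]")
        idx = np.minimum(np.floor(t_arr * self.n1 + 1e-9).astype(int), self.n1)
        out = self.roc_values[idx]
        out = np.where(t_arr <= 0.0, 0.0, out)
        out = np.where(t_arr >= 1.0, 1.0, out)
        if t_arr.ndim == 0:
            return float(out)
        return out

    @property
    def fit_grid(self) -> np.ndarray:
        """The attainable FPR values ``{i/n1}`` used as evaluation points."""
        return self.fpr_grid

    @property
    def auc(self) -> float:
        """Exact area under the step function.

        Equals the fraction of (X, Y) pairs with ``Y > X`` (the
        Mann-Whitney statistic under the strict-inequality convention
        implied by the right-continuous step curve; ties between the two
        groups are not split).
        """
        return float(np.mean(self.roc_values[:-1]))


def empirical_roc(sample: Sample) -> EmpiricalROC:
    """Build the empirical ROC step function for a two-group sample."""
    return EmpiricalROC.from_sample(sample)


def auc(curve, grid_size: int = 1001) -> float:
    """Trapezoidal area under an evaluable curve on [0, 1].

    ``grid_size`` defaults to 1001 points, giving integration error well
    below the third decimal for monotone bounded curves.  For the exact
    area of an :class:`EmpiricalROC` use its ``auc`` property.
    """
    if grid_size < 2:
        raise ValueError("grid_size must be at least 2")
    grid = np.linspace(0.0, 1.0, grid_size)
    values = np.asarray(curve(grid), dtype=float)
    return float(np.trapezoid(values, grid))


def flip_marker(sample: Sample) -> Sample:
    """Reverse marker orientation so larger values indicate disease."""
    return sample.flip()
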