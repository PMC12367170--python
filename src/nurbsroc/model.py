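"""NURBS-based nonparametric ROC curve estimation.

The estimator smooths the empirical ROC curve with a rational B-spline

    ROC_hat(t) = sum_k P_k  w_k N_{k,m}(t) / sum_j w_j N_{j,m}(t)

whose control values ``P_k = ROC_n(theta_k)`` are the empirical ROC
evaluated at the averaged knot positions ``theta_k``.  The weights ``w``
are fitted by bounded least squares (L-BFGS-B, each weight bounded below
by 1e-6) against the empirical curve's operating points — the pairs
``(FPR_j, TPR_j)`` attained at the observed thresholds — and the number
of interior knots is chosen by AIC

    log(mean squared residual) + 2 (m + l) / N,

``N`` being the number of evaluation points on the empirical curve.

With no interior knots and equal weights the estimator is exactly the
Bernstein-polynomial ROC estimator.  The module follows the
statsmodels convention: :class:`NURBSROC` / :class:`BernsteinROC` are
model objects built from the data, and ``fit()`` returns a
:class:`NURBSROCResults` carrying the estimate, diagnostics and a
``summary()`` table.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import isotonic_regression, minimize

from .bspline import (
    KnotVector,
    bspline_basis_matrix,
    build_knot_vector,
    greville_abscissae,
    rational_basis_matrix,
)
from .empirical import EmpiricalROC, Sample, auc as _trapezoid_auc, empirical_roc

__all__ = [
    "FitConfig",
    "NURBSROC",
    "BernsteinROC",
    "NURBSROCResults",
    "adaptive_degree",
    "control_points",
    "fit_weights",
    "aic_score",
    "select_knots_aic",
]

WEIGHT_LOWER_BOUND = 1e-6
#: floor for the mean squared residual inside the AIC, guarding log(0)
AIC_MSE_FLOOR = 1e-300


@dataclass(frozen=True)
class FitConfig:
    """Tuning parameters of the NURBS fit.

    Parameters
    ----------
    degree : int or None
        Spline degree ``m``.  ``None`` with ``adaptive=True`` applies the
        sample-size rule ``m = 0.5 * n2**(2/3)``.
    adaptive : bool
        Use the adaptive degree rule instead of a fixed degree.
    weight_lower_bound : float
        Box constraint keeping every weight strictly positive (1e-6).
    max_interior : int
        Cap on the number of interior knots searched by AIC.
    maxiter : int
        Iteration cap for the bounded quasi-Newton weight optimization.
    grid : ndarray or None
        Evaluation points for the least-squares objective and the AIC;
        defaults to the FPR coordinates of the empirical curve's
        operating points (with the step values as targets when an
        explicit grid is supplied).
    rng_seed : int or None
        Seed for bootstrap resampling in ``conf_band``.
    """

    degree: int | None = 6
    adaptive: bool = False
    weight_lower_bound: float = WEIGHT_LOWER_BOUND
    max_interior: int = 10
    maxiter: int = 500
    grid: np.ndarray | None = None
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        if self.weight_lower_bound <= 0.0:
            raise ValueError("weight_lower_bound must be positive")
        if self.max_interior < 0:
            raise ValueError("max_interior must be non-negative")
        if not self.adaptive and (self.degree is None or self.degree < 1):
            raise ValueError("degree must be an integer >= 1")


def adaptive_degree(n2: int) -> int:
    """Data-driven spline degree ``m = 0.5 * n2**(2/3)``.

    Rounded half-up and floored at 1, e.g. ``n2 = 100`` gives
    ``round(10.77) = 11``.
    """
    if n2 < 1:
        raise ValueError("n2 must be at least 1")
    return max(1, int(math.floor(0.5 * n2 ** (2.0 / 3.0) + 0.5)))


def control_points(emp: EmpiricalROC, kv: KnotVector) -> tuple[np.ndarray, bool]:
    """Control values ``P_k = ROC_n(theta_k)`` at the averaged knot positions.

    Returns the vector and a flag telling whether an isotonic
    (pool-adjacent-violators) projection was applied.  For a genuine
    empirical ROC the values are automatically non-decreasing with
    ``P_0 = 0`` and ``P_last = 1``; the projection only ever touches
    non-monotone user-supplied curves.
    """
    theta = greville_abscissae(kv)
    p = np.asarray(emp(theta), dtype=float)
    adjusted = False
    if np.any(np.diff(p) < 0.0):
        p = np.clip(isotonic_regression(p).x, 0.0, 1.0)
        adjusted = True
    return p, adjusted


def _objective_factory(basis: np.ndarray, p: np.ndarray, target: np.ndarray):
    """Least-squares objective in the weights, with analytic gradient.

    With ``d_i = sum_k B_ik w_k`` and ``f_i = sum_k B_ik P_k w_k / d_i``
    the objective is ``sum_i (r_i - f_i)^2`` and

        d obj / d w_k = -2 sum_i (r_i - f_i) B_ik (P_k - f_i) / d_i.
    """
    bp = basis * p

    def objective(w):
        denom = basis @ w
        fitted = (bp @ w) / denom
        resid = target - fitted
        value = float(resid @ resid)
        grad = -2.0 * ((resid / denom)[:, None] * (basis * (p[None, :] - fitted[:, None]))).sum(axis=0)
        return value, grad

    return objective


def fit_weights(
    emp: EmpiricalROC,
    kv: KnotVector,
    p: np.ndarray,
    *,
    grid: np.ndarray | None = None,
    target: np.ndarray | None = None,
    weight_lower_bound: float = WEIGHT_LOWER_BOUND,
    maxiter: int = 500,
    start: np.ndarray | None = None,
) -> tuple[np.ndarray, float, dict]:
    """Fit the NURBS weights by bounded least squares against ``ROC_n``.

    By default the residuals are taken at the empirical curve's operating
    points: the sensitivity ``TPR_j`` attained at each observed threshold
    is matched at ``t = FPR_j``.  An explicit ``grid`` (with the step
    values as targets) may be supplied instead.

    Starts from the equal-weight (plain B-spline) solution and minimizes
    the summed squared deviation with L-BFGS-B under
    ``w_k >= weight_lower_bound``.  The achieved objective is never worse
    than the equal-weight start: if the optimizer fails to improve, the
    start is returned.

    Returns ``(weights, objective, info)`` where ``info`` records the
    optimizer status and the equal-weight objective.
    """
    if grid is None:
        grid = emp.fpr_points
        if target is None:
            target = emp.tpr_points
    grid = np.asarray(grid, dtype=float)
    if target is None:
        target = np.asarray(emp(grid), dtype=float)
    else:
        target = np.asarray(target, dtype=float)
    basis = bspline_basis_matrix(kv, grid)
    objective = _objective_factory(basis, p, target)

    w0 = np.ones(kv.n_basis) if start is None else np.asarray(start, dtype=float)
    f0, _ = objective(w0)
    res = minimize(
        objective,
        w0,
        jac=True,
        method="L-BFGS-B",
        bounds=[(weight_lower_bound, None)] * kv.n_basis,
        options={"maxiter": maxiter},
    )
    info = {
        "converged": bool(res.success),
        "message": str(res.message),
        "n_iter": int(res.nit),
        "start_objective": f0,
    }
    if res.fun <= f0:
        return np.asarray(res.x, dtype=float), float(res.fun), info
    # monotone-improvement contract: fall back to the equal-weight start
    info["converged"] = False
    info["message"] = "optimizer did not improve on the equal-weight start"
    return w0, f0, info


def aic_score(emp: EmpiricalROC, model, grid, target=None) -> float:
    """AIC of a fitted curve: ``log(MSE) + 2 (m + l) / N``.

    ``model`` must be evaluable on the grid and expose ``n_control``
    (the number of control points ``m + l``).  ``target`` defaults to the
    empirical step values at the grid.  The MSE is floored at 1e-300 so a
    perfect fit yields a finite score.
    """
    grid = np.asarray(grid, dtype=float)
    if target is None:
        target = np.asarray(emp(grid), dtype=float)
    resid = np.asarray(target, dtype=float) - np.asarray(model(grid), dtype=float)
    mse = max(float(np.mean(resid**2)), AIC_MSE_FLOOR)
    return math.log(mse) + 2.0 * model.n_control / grid.size


def _interior_candidates(fpr_values: np.ndarray, n_interior: int) -> np.ndarray | None:
    """Interior knots at equally spaced percentile levels of the FPRs.

    Levels ``j / l`` for ``j = 1, ..., l-1`` with the linear-interpolation
    quantile; returns ``None`` when the candidate degenerates (knots not
    strictly increasing inside (0, 1))."""
    if n_interior == 0:
        return np.empty(0)
    l = n_interior + 1
    levels = np.arange(1, l) / l
    knots = np.quantile(fpr_values, levels)
    if np.any(knots <= 0.0) or np.any(knots >= 1.0) or np.any(np.diff(knots) <= 0.0):
        return None
    return knots


def select_knots_aic(emp: EmpiricalROC, m: int, cfg: FitConfig | None = None) -> "NURBSROCResults":
    """Fit the NURBS estimator for every candidate interior-knot count and
    keep the AIC minimizer.

    Candidates are ``l - 1 = 0, ..., min(max_interior, N - m - 1)`` with
    knots at equally spaced percentile levels ``j/l`` of the observed FPR
    coordinates (duplicates included, so knots concentrate where the
    curve has many operating points); degenerate candidates (coincident
    knots) are skipped.  Ties favour the smaller knot count.
    """
    if cfg is None:
        cfg = FitConfig(degree=m)
    if cfg.grid is None:
        grid = emp.fpr_points
        target = emp.tpr_points
    else:
        grid = np.asarray(cfg.grid, dtype=float)
        target = np.asarray(emp(grid), dtype=float)
    n_eval = grid.size
    cap = min(cfg.max_interior, n_eval - m - 1)
    candidates = range(0, max(cap, 0) + 1)

    best = None
    trace = []
    for n_int in candidates:
        interior = _interior_candidates(grid, n_int)
        if interior is None:
            continue
        kv = build_knot_vector(m, interior)
        p, adjusted = control_points(emp, kv)
        w, obj, info = fit_weights(
            emp,
            kv,
            p,
            grid=grid,
            target=target,
            weight_lower_bound=cfg.weight_lower_bound,
            maxiter=cfg.maxiter,
        )
        res = NURBSROCResults(
            kv=kv,
            control_abscissae=greville_abscissae(kv),
            control_values=p,
            weights=w,
            objective=obj,
            emp=emp,
            isotonic_adjusted=adjusted,
            optimizer_info=info,
        )
        score = aic_score(emp, res, grid, target)
        res.aic = score
        trace.append((n_int, score))
        if best is None or score < best.aic:
            best = res
    if best is None:  # degenerate curve: no valid candidate, use l - 1 = 0
        kv = build_knot_vector(m, ())
        p, adjusted = control_points(emp, kv)
        w, obj, info = fit_weights(emp, kv, p, grid=grid, target=target,
                                   weight_lower_bound=cfg.weight_lower_bound,
                                   maxiter=cfg.maxiter)
        best = NURBSROCResults(
            kv=kv,
            control_abscissae=greville_abscissae(kv),
            control_values=p,
            weights=w,
            objective=obj,
            emp=emp,
            isotonic_adjusted=adjusted,
            optimizer_info=info,
        )
        best.aic = aic_score(emp, best, grid, target)
        trace.append((0, best.aic))
    best.aic_trace = trace
    return best


class NURBSROC:
    """NURBS model for a two-sample ROC curve.

    Parameters
    ----------
    x, y : array_like
        Marker values for the healthy and diseased groups.
    degree : int, default 6
        Spline degree ``m``; ignored when ``adaptive=True``.
    adaptive : bool, default False
        Choose the degree from the diseased-group size via
        :func:`adaptive_degree`.
    max_interior : int, default 10
        Largest interior-knot count searched by AIC.
    weight_lower_bound : float, default 1e-6
        Lower box bound on every weight.
    flip : bool, default False
        Negate the marker first (negative predictor).
    seed : int, optional
        Seed for bootstrap confidence bands.

    Examples
    --------
    >>> model = NURBSROC(x_healthy, y_diseased, degree=4)
    >>> res = model.fit()
    >>> res.auc(), res.n_interior
    """

    def __init__(
        self,
        x=None,
        y=None,
        *,
        sample: Sample | None = None,
        degree: int | None = 6,
        adaptive: bool = False,
        max_interior: int = 10,
        weight_lower_bound: float = WEIGHT_LOWER_BOUND,
        maxiter: int = 500,
        flip: bool = False,
        seed: int | None = None,
    ) -> None:
        if sample is None:
            sample = Sample(x, y)
        if flip:
            sample = sample.flip()
        self.sample = sample
        self.config = FitConfig(
            degree=degree if not adaptive else None,
            adaptive=adaptive,
            weight_lower_bound=weight_lower_bound,
            max_interior=max_interior,
            maxiter=maxiter,
            rng_seed=seed,
        )
        self.emp = empirical_roc(sample)

    @classmethod
    def from_dataframe(cls, data, value_col: str = "value", status_col: str = "status", **kwargs):
        """Build the model from a tidy table with a marker column and a
        binary disease-status column (0 = healthy, 1 = diseased)."""
        from .io import sample_from_frame

        return cls(sample=sample_from_frame(data, value_col, status_col), **kwargs)

    @property
    def degree(self) -> int:
        if self.config.adaptive:
            return adaptive_degree(self.sample.n2)
        return int(self.config.degree)

    def fit(self) -> "NURBSROCResults":
        """Select interior knots by AIC and fit the weights; returns results."""
        res = select_knots_aic(self.emp, self.degree, self.config)
        res.model = self
        return res


class BernsteinROC(NURBSROC):
    """Bernstein-polynomial ROC estimator of degree ``m``.

    The special case of the NURBS estimator with no interior knots and
    equal weights: ``sum_k ROC_n(k/m) C(m,k) t^k (1-t)^(m-k)``.  ``fit``
    involves no optimization.
    """

    def fit(self) -> "NURBSROCResults":
        m = self.degree
        kv = build_knot_vector(m, ())
        p, adjusted = control_points(self.emp, kv)
        w = np.ones(kv.n_basis)
        grid = self.emp.fpr_points
        target = self.emp.tpr_points
        basis = bspline_basis_matrix(kv, grid)
        resid = target - basis @ p
        res = NURBSROCResults(
            kv=kv,
            control_abscissae=greville_abscissae(kv),
            control_values=p,
            weights=w,
            objective=float(resid @ resid),
            emp=self.emp,
            isotonic_adjusted=adjusted,
            optimizer_info={"converged": True, "message": "equal weights (no optimization)",
                            "n_iter": 0, "start_objective": float(resid @ resid)},
        )
        res.aic = aic_score(self.emp, res, grid, target)
        res.aic_trace = [(0, res.aic)]
        res.model = self
        return res


@dataclass
class NURBSROCResults:
    """Fitted NURBS ROC curve with diagnostics.

    Evaluable as a function on [0, 1]; interpolates (0, 0) and (1, 1)
    by construction of the clamped basis.
    """

    kv: KnotVector
    control_abscissae: np.ndarray
    control_values: np.ndarray
    weights: np.ndarray
    objective: float
    emp: EmpiricalROC | None = None
    aic: float = math.nan
    isotonic_adjusted: bool = False
    optimizer_info: dict = field(default_factory=dict)
    aic_trace: list = field(default_factory=list)
    model: NURBSROC | None = None

    @property
    def degree(self) -> int:
        return self.kv.degree

    @property
    def n_interior(self) -> int:
        return len(self.kv.interior)

    @property
    def n_control(self) -> int:
        return self.kv.n_basis

    def predict(self, t):
        """Evaluate the fitted ROC curve at ``t`` (scalar or vector in [0, 1])."""
        t_arr = np.asarray(t, dtype=float)
        basis = rational_basis_matrix(self.kv, self.weights, t_arr)
        out = basis @ self.control_values
        if t_arr.ndim == 0:
            return float(out[0])
        return out

    __call__ = predict

    def auc(self, grid_size: int = 1001) -> float:
        """Area under the fitted curve (trapezoidal, ``grid_size`` points)."""
        return _trapezoid_auc(self.predict, grid_size)

    def conf_band(
        self,
        B: int = 1000,
        level: float = 0.95,
        grid=None,
        seed: int | None = None,
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Pointwise percentile bootstrap confidence band.

        Resamples each group with replacement, refits the same estimator,
        and takes pointwise percentiles of the ``B`` refitted curves.

        Returns ``(grid, lower, upper)``.
        """
        if self.model is None:
            raise ValueError("bootstrap requires the originating model (data)")
        if B < 2:
            raise ValueError("B must be at least 2")
        if not 0.0 < level < 1.0:
            raise ValueError("level must lie in (0, 1)")
        if grid is None:
            grid = np.linspace(0.0, 1.0, 101)
        grid = np.asarray(grid, dtype=float)
        if seed is None:
            seed = self.model.config.rng_seed
        rng = np.random.default_rng(seed)
        sample = self.model.sample
        curves = np.empty((B, grid.size))
        cls = type(self.model)
        for b in range(B):
            xb = rng.choice(sample.x, size=sample.n1, replace=True)
            yb = rng.choice(sample.y, size=sample.n2, replace=True)
            boot = cls(
                xb,
                yb,
                degree=None if self.model.config.adaptive else self.model.config.degree,
                adaptive=self.model.config.adaptive,
                max_interior=self.model.config.max_interior,
                weight_lower_bound=self.model.config.weight_lower_bound,
            ).fit()
            curves[b] = boot.predict(grid)
        alpha = 1.0 - level
        lower = np.quantile(curves, alpha / 2.0, axis=0)
        upper = np.quantile(curves, 1.0 - alpha / 2.0, axis=0)
        return grid, lower, upper

    def summary(self) -> str:
        """Plain-text summary table in the statsmodels spirit."""
        lines = [
            "NURBS ROC estimation results",
            "=" * 46,
            f"degree (m):            {self.degree}",
            f"interior knots (l-1):  {self.n_interior}",
            f"control points (m+l):  {self.n_control}",
            f"least-squares obj.:    {self.objective:.6g}",
            f"AIC:                   {self.aic:.6g}",
            f"AUC (trapezoid):       {self.auc():.4f}",
            f"optimizer converged:   {self.optimizer_info.get('converged', True)}",
        ]
        if self.emp is not None:
            lines.append(f"n1, n2:                {self.emp.n1}, {self.emp.n2}")
            lines.append(f"empirical AUC:         {self.emp.auc:.4f}")
        if self.isotonic_adjusted:
            lines.append("note: control points were isotonically projected")
        lines.append("=" * 46)
        return "\n".join(lines)

    def plot(self, ax=None, grid=None, band: tuple | None = None, **kwargs):
        """Plot the fitted curve (and optionally a confidence band)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if grid is None:
            grid = np.linspace(0.0, 1.0, 201)
        ax.plot(grid, self.predict(grid), **kwargs)
        if band is not None:
            bgrid, lower, upper = band
            ax.fill_between(bgrid, lower, upper, alpha=0.25)
        ax.plot([0, 1], [0, 1], ls=":", c="grey", lw=0.8)
        ax.set_xlabel("false-positive rate")
        ax.set_ylabel("true-positive rate")
        return ax

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "degree": self.degree,
            "interior_knots": list(self.kv.interior),
            "weights": self.weights.tolist(),
            "control_abscissae": self.control_abscissae.tolist(),
            "control_values": self.control_values.tolist(),
            "aic": self.aic,
            "objective": self.objective,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_dict(cls, payload: dict) -> "NURBSROCResults":
        kv = build_knot_vector(int(payload["degree"]), payload["interior_knots"])
        res = cls(
            kv=kv,
            control_abscissae=np.asarray(payload["control_abscissae"], dtype=float),
            control_values=np.asarray(payload["control_values"], dtype=float),
            weights=np.asarray(payload["weights"], dtype=float),
            objective=float(payload["objective"]),
        )
        res.aic = float(payload["aic"])
        return res

    @classmethod
    def from_json(cls, text: str) -> "NURBSROCResults":
        return cls.from_dict(json.loads(text))
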