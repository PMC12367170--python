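"""Monte Carlo benchmarking of ROC curve estimators.

Six two-group sampling scenarios with known true ROC curves:

    S1: X ~ Normal(0, 1),    Y ~ Normal(1, 1)
    S2: X ~ Normal(0, 1),    Y ~ Normal(2, 1.2)
    S3: X ~ Exponential(2),  Y ~ Exponential(1)      (rate parameterization)
    S4: X ~ Gamma(0.5, 1),   Y ~ Gamma(0.5, 4)       (shape, scale)
    S5: X ~ Normal(2, 1),    Y ~ Gamma(2, 2)
    S6: X ~ Normal(1, 1),    Y ~ Gamma(2, 2)

Gamma distributions use the shape-scale parameterization so that the
diseased group is stochastically larger (AUC > 0.5), matching the
convention that higher marker values indicate disease.  Normal-vs-normal
scenarios have the binormal closed form Phi(a + b Phi^{-1}(t)) with
``a = (mu_Y - mu_X)/sigma_Y`` and ``b = sigma_X/sigma_Y``; the
exponential pair gives ``t**(rate_Y/rate_X)``; the remaining true curves
are evaluated numerically from 1 - G(F^{-1}(1 - t)).

Estimator accuracy is measured by the averaged squared error

    ASE = (1/N) sum_i (ROC_hat(t_i) - ROC(t_i))^2.

By default the evaluation points ``t_i`` are the FPR coordinates of the
replicate's empirical ROC operating points — one per distinct pooled
sample value plus the (0, 0) endpoint — so regions where the sample puts
many thresholds (e.g. the steep low-FPR corner when the groups are well
separated) carry proportionally more weight; the empirical estimator
itself contributes its attained sensitivity ``TPR_i`` at each point.  A
fixed uniform grid (``ASE_GRID``) can be supplied instead.  All
estimators in a replicate share one sample (paired design) so that
per-replicate ASE differences support paired t-tests.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats

from .empirical import EmpiricalROC, Sample, empirical_roc
from .model import BernsteinROC, NURBSROC

__all__ = [
    "Scenario",
    "SCENARIOS",
    "ASE_GRID",
    "ESTIMATORS",
    "register_estimator",
    "binormal_roc",
    "sample_scenario",
    "true_roc",
    "ase",
    "run_study",
    "StudyResult",
    "bootstrap_ci_mean",
    "paired_t_test",
]

#: default evaluation grid for the averaged squared error; endpoints are
#: excluded because every estimator interpolates (0,0) and (1,1) anyway
ASE_GRID = np.linspace(0.005, 0.995, 101)


def binormal_roc(a: float, b: float) -> Callable:
    """Closed-form ROC for two normal groups: Phi(a + b * Phi^{-1}(t))."""

    def curve(t):
        t_arr = np.asarray(t, dtype=float)
        with np.errstate(divide="ignore"):
            out = stats.norm.cdf(a + b * stats.norm.ppf(t_arr))
        out = np.where(t_arr <= 0.0, 0.0, np.where(t_arr >= 1.0, 1.0, out))
        return out if t_arr.ndim else float(out)

    return curve


def _power_roc(exponent: float) -> Callable:
    """ROC of two exponentials: t ** (rate_Y / rate_X)."""

    def curve(t):
        t_arr = np.asarray(t, dtype=float)
        out = t_arr**exponent
        return out if t_arr.ndim else float(out)

    return curve


@dataclass(frozen=True)
class Scenario:
    """A two-group sampling design with a known true ROC curve."""

    label: str
    x_dist: object  # frozen scipy.stats distribution (healthy)
    y_dist: object  # frozen scipy.stats distribution (diseased)
    closed_form: Callable | None = None

    def sample(self, n1: int, n2: int, rng: np.random.Generator) -> Sample:
        if n1 < 1 or n2 < 1:
            raise ValueError("sample sizes must be at least 1")
        return Sample(self.x_dist.rvs(size=n1, random_state=rng),
                      self.y_dist.rvs(size=n2, random_state=rng))

    def true_roc(self, t):
        if self.closed_form is not None:
            return self.closed_form(t)
        t_arr = np.asarray(t, dtype=float)
        inner = np.clip(1.0 - t_arr, 0.0, 1.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            out = 1.0 - self.y_dist.cdf(self.x_dist.ppf(inner))
        out = np.where(t_arr <= 0.0, 0.0, np.where(t_arr >= 1.0, 1.0, out))
        return out if t_arr.ndim else float(out)


SCENARIOS: dict[str, Scenario] = {
    "S1": Scenario("S1", stats.norm(0, 1), stats.norm(1, 1), binormal_roc(1.0, 1.0)),
    "S2": Scenario("S2", stats.norm(0, 1), stats.norm(2, 1.2),
                   binormal_roc(2.0 / 1.2, 1.0 / 1.2)),
    "S3": Scenario("S3", stats.expon(scale=1 / 2), stats.expon(scale=1),
                   _power_roc(1.0 / 2.0)),
    "S4": Scenario("S4", stats.gamma(0.5, scale=1), stats.gamma(0.5, scale=4)),
    "S5": Scenario("S5", stats.norm(2, 1), stats.gamma(2, scale=2)),
    "S6": Scenario("S6", stats.norm(1, 1), stats.gamma(2, scale=2)),
}


def sample_scenario(sc: Scenario | str, n1: int, n2: int, rng_seed) -> Sample:
    """Draw one two-group sample from a scenario; deterministic in the seed."""
    sc = _resolve_scenario(sc)
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    return sc.sample(n1, n2, rng)


def true_roc(sc: Scenario | str, t):
    """Evaluate a scenario's true ROC curve at ``t``."""
    return _resolve_scenario(sc).true_roc(t)


def _resolve_scenario(sc) -> Scenario:
    if isinstance(sc, Scenario):
        return sc
    try:
        return SCENARIOS[sc]
    except KeyError:
        raise ValueError(
            f"unknown scenario {sc!r}; valid labels: {sorted(SCENARIOS)}"
        ) from None


def ase(estimated, sc: Scenario | str | Callable, grid=None) -> float:
    """Averaged squared error of a curve against a scenario's true ROC."""
    grid = ASE_GRID if grid is None else np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("ASE grid must be non-empty")
    truth = sc(grid) if callable(sc) and not isinstance(sc, Scenario) else true_roc(sc, grid)
    diff = np.asarray(estimated(grid), dtype=float) - np.asarray(truth, dtype=float)
    return float(np.mean(diff**2))


# -- estimator registry ---------------------------------------------------

def _nurbs_estimator(degree=None, adaptive=False):
    def fit(sample: Sample):
        return NURBSROC(sample=sample, degree=degree, adaptive=adaptive).fit()

    return fit


def _bernstein_estimator(degree=None, adaptive=False):
    def fit(sample: Sample):
        return BernsteinROC(sample=sample, degree=degree, adaptive=adaptive).fit()

    return fit


#: named estimators usable in ``run_study``; external competitors (such as
#: a kernel-smoothed ROC) can be attached with :func:`register_estimator`
ESTIMATORS: dict[str, Callable[[Sample], Callable]] = {
    "empirical": empirical_roc,
    "bp2": _bernstein_estimator(2),
    "bp4": _bernstein_estimator(4),
    "bp6": _bernstein_estimator(6),
    "nb2": _nurbs_estimator(2),
    "nb4": _nurbs_estimator(4),
    "nb6": _nurbs_estimator(6),
    "bp_adaptive": _bernstein_estimator(adaptive=True),
    "nb_adaptive": _nurbs_estimator(adaptive=True),
}


def register_estimator(name: str, fit: Callable[[Sample], Callable]) -> None:
    """Register an external estimator (a callable Sample -> evaluable curve)."""
    ESTIMATORS[name] = fit


def _replicate_seed(base_seed: int, label: str, n1: int, n2: int, rep: int):
    key = zlib.crc32(label.encode("utf-8")) % (2**31)
    return np.random.SeedSequence([int(base_seed), key, int(n1), int(n2), int(rep)])


@dataclass
class StudyResult:
    """Tidy per-replicate ASE values plus summary machinery.

    ``grid`` is None when the ASE was taken at each replicate's own ROC
    operating points (the default), else the fixed grid used.
    """

    data: pd.DataFrame  # columns: scenario, n1, n2, estimator, replicate, ase
    base_seed: int
    grid: np.ndarray | None

    def summary(self, B: int = 1000, level: float = 0.95, seed: int | None = None) -> pd.DataFrame:
        """Mean ASE with percentile-bootstrap confidence interval per cell."""
        if seed is None:
            seed = self.base_seed
        rows = []
        for (scen, n1, n2, est), grp in self.data.groupby(
            ["scenario", "n1", "n2", "estimator"], sort=False
        ):
            vals = grp["ase"].dropna().to_numpy()
            lo, hi = bootstrap_ci_mean(vals, B=B, level=level,
                                       rng_seed=np.random.SeedSequence([int(seed), zlib.crc32(f"{scen}:{n1}:{n2}:{est}".encode()) % (2**31)]))
            rows.append({"scenario": scen, "n1": n1, "n2": n2, "estimator": est,
                         "reps": vals.size, "mean_ase": vals.mean(),
                         "ci_lower": lo, "ci_upper": hi})
        return pd.DataFrame(rows)

    def mean_ase(self, scenario: str, n1: int, n2: int, estimator: str) -> float:
        sel = self.data.query(
            "scenario == @scenario and n1 == @n1 and n2 == @n2 and estimator == @estimator"
        )["ase"].dropna()
        return float(sel.mean())

    def paired_pvalue(self, scenario: str, n1: int, n2: int, est_a: str, est_b: str) -> float:
        """Paired t-test p-value on per-replicate ASE of two estimators."""
        wide = (
            self.data.query("scenario == @scenario and n1 == @n1 and n2 == @n2")
            .pivot(index="replicate", columns="estimator", values="ase")[[est_a, est_b]]
            .dropna()
        )
        return paired_t_test(wide[est_a].to_numpy(), wide[est_b].to_numpy())


def run_study(
    scenarios,
    size_pairs,
    reps: int,
    estimators,
    base_seed: int = 0,
    grid=None,
    progress: Callable[[str], None] | None = None,
) -> StudyResult:
    """Paired Monte Carlo comparison of ROC estimators.

    For every scenario, size pair and replicate one sample is drawn and
    **all** estimators are fitted to it, so per-replicate differences are
    paired.  A failing estimator is recorded as NaN for that replicate.
    Fully reproducible from ``base_seed``.
    """
    if reps < 1:
        raise ValueError("reps must be at least 1")
    roc_point_grid = grid is None
    if not roc_point_grid:
        grid = np.asarray(grid, dtype=float)
    scenario_objs = [_resolve_scenario(s) for s in scenarios]
    fitters = {}
    for name in estimators:
        if callable(name):
            fitters[getattr(name, "__name__", repr(name))] = name
        elif name in ESTIMATORS:
            fitters[name] = ESTIMATORS[name]
        else:
            raise ValueError(
                f"unknown estimator {name!r}; valid names: {sorted(ESTIMATORS)}"
            )

    records = []
    for sc in scenario_objs:
        for n1, n2 in size_pairs:
            if progress is not None:
                progress(f"{sc.label} (n1={n1}, n2={n2}): {reps} replicates")
            if not roc_point_grid:
                truth = sc.true_roc(grid)
            for r in range(reps):
                rng = np.random.default_rng(_replicate_seed(base_seed, sc.label, n1, n2, r))
                sample = sc.sample(n1, n2, rng)
                emp = empirical_roc(sample)
                if roc_point_grid:
                    eval_t = emp.fpr_points
                    truth = sc.true_roc(eval_t)
                else:
                    eval_t = grid
                for name, fitter in fitters.items():
                    try:
                        curve = fitter(sample)
                        if roc_point_grid and isinstance(curve, EmpiricalROC):
                            # the empirical curve's own operating points
                            values = curve.tpr_points
                        else:
                            values = np.asarray(curve(eval_t), dtype=float)
                        err = float(np.mean((values - truth) ** 2))
                    except Exception:  # pragma: no cover - defensive
                        import warnings

                        warnings.warn(f"estimator {name} failed on replicate {r} of {sc.label}")
                        err = np.nan
                    records.append(
                        {"scenario": sc.label, "n1": n1, "n2": n2,
                         "estimator": name, "replicate": r, "ase": err}
                    )
    return StudyResult(
        pd.DataFrame.from_records(records), int(base_seed),
        None if roc_point_grid else grid,
    )


def bootstrap_ci_mean(values, B: int = 1000, level: float = 0.95, rng_seed=None) -> tuple[float, float]:
    """Percentile bootstrap confidence interval for the mean."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least two values")
    if B < 2:
        raise ValueError("B must be at least 2")
    rng = np.random.default_rng(rng_seed)
    idx = rng.integers(0, v.size, size=(B, v.size))
    means = v[idx].mean(axis=1)
    alpha = 1.0 - level
    return float(np.quantile(means, alpha / 2.0)), float(np.quantile(means, 1.0 - alpha / 2.0))


def paired_t_test(a, b) -> float:
    """Two-sided paired t-test p-value for mean difference zero.

    Degenerate cases: identical vectors give p = 1; zero variance of the
    differences with a non-zero mean gives the p -> 0 limit.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need two equal-length vectors with at least two pairs")
    d = a - b
    if np.allclose(d, 0.0):
        return 1.0
    if np.std(d, ddof=1) == 0.0:
        return 0.0
    return float(stats.ttest_rel(a, b).pvalue)
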