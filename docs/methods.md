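# Methods

## Model

Two independent samples of a continuous diagnostic marker are observed:
`X_1, ..., X_n1` from the healthy group (CDF `F`) and `Y_1, ..., Y_n2`
from the diseased group (CDF `G`), oriented so that larger values
indicate disease (`flip_marker` / `--flip` negates a negative predictor).
The target of estimation is the ROC curve `ROC(t) = 1 − G(F⁻¹(1 − t))`.

The estimator is a rational B-spline (NURBS) of degree `m` on a clamped
knot vector

    T = (0, ..., 0, t_{m+1} < ... < t_{m+l−1}, 1, ..., 1)

with 0 and 1 each repeated `m + 1` times and `l − 1` interior knots:

    ROĈ(t) = Σ_{k=0}^{m+l−1} P_k R_{k,m}(t),
    R_{k,m}(t) = w_k N_{k,m}(t) / Σ_j w_j N_{j,m}(t),

where the `N_{k,m}` follow the Cox–de Boor recursion with the 0/0 = 0
convention for repeated knots and the final degree-0 interval closed at
t = 1 (so the partition of unity also holds at 1). Control values are
the empirical ROC at the averaged knot (Greville) positions,
`P_k = ROCₙ(θ_k)`, `θ_k = (1/m) Σ_{i=1..m} t_{i+k}`. Clamping makes the
curve interpolate (0, 0) and (1, 1) exactly, and non-decreasing control
values with positive weights keep the fitted curve monotone in practice
(monotonicity is additionally verified post hoc on a fine grid in the
test suite rather than assumed, since rational splines with unequal
weights do not carry a simple shape guarantee).

## Empirical ROC and its operating points

`EmpiricalROC` stores two views of the plug-in estimator:

* the right-continuous step function on the attained FPR grid `{i/n1}`
  (type-1/left-continuous generalized-inverse quantile convention, which
  makes the exact step-function AUC equal the strict-inequality
  Mann–Whitney statistic; ties between groups are absorbed by the ECDF
  steps, no jitter). Evaluation anchors `ROCₙ(0) = 0` and `ROCₙ(1) = 1`,
  as for any ROC curve, so control points inherit `P_0 = 0`,
  `P_last = 1`;
* the **operating points** `(FPR_j, TPR_j)`: one pair per distinct pooled
  marker value used as a classification threshold (counted with ≥), plus
  the trivial (0, 0) point — `N ≈ n1 + n2 + 1` points. Several points
  share an FPR where consecutive thresholds are diseased-group values
  (vertical runs of the staircase), so regions dense in observations —
  typically the steep low-FPR corner of a well-separated marker — carry
  proportionally many points.

All data-driven steps operate on the operating points, which is what an
implementation built on standard per-threshold ROC software produces and
the choice under which the package's Monte Carlo results are calibrated:

* **weights** solve `min_w Σ_j (TPR_j − ROĈ(FPR_j))²` subject to
  `w_k ≥ 10⁻⁶` (numerical stability; strictly positive rational basis),
  via L-BFGS-B from the equal-weight start `w = 1` with an analytic
  gradient. The rational basis is invariant to rescaling `w`, so weights
  are identified only up to a constant; all comparisons are between
  fitted curves, never raw weights. If the optimizer fails to improve on
  the start, the equal-weight solution is returned (monotone-improvement
  contract);
* **interior knots** for a candidate count `l − 1` sit at the
  `j/l`-quantiles (linear interpolation) of the FPR coordinates,
  duplicates included; candidates whose knots collapse onto each other or
  the boundary are skipped;
* the **knot count** minimises `AIC = log(MSE) + 2(m + l)/N` over
  `l − 1 = 0, ..., min(10, N − m − 1)` (ties favour fewer knots; the MSE
  is floored at 1e−300 to keep a perfect fit finite). The cap of 10
  bounds cost and was not observed to bind the achieved accuracy.

With `l = 1` (no interior knots) and equal weights the estimator is
exactly the Bernstein-polynomial ROC estimator
`Σ_k ROCₙ(k/m) C(m,k) tᵏ (1−t)^{m−k}` (`BernsteinROC`). The adaptive
degree rule is `m = 0.5 · n2^{2/3}`, rounded half-up and floored at 1
(n2 = 100 gives m = 11).

## Uncertainty

Pointwise confidence bands resample each group with replacement, refit
the full pipeline (knot selection included), and take pointwise
percentile intervals over `B` refits (default B = 1000, level 0.95),
seeded for reproducibility.

## Synthetic-data scenarios and the simulation protocol

Six scenarios with known true ROC curves define the benchmarking
conditions:

| label | healthy X | diseased Y | true ROC |
|---|---|---|---|
| S1 | Normal(0, 1) | Normal(1, 1) | Φ(a + bΦ⁻¹(t)), a = 1, b = 1 |
| S2 | Normal(0, 1) | Normal(2, 1.2) | binormal, a = 2/1.2, b = 1/1.2 |
| S3 | Exponential(rate 2) | Exponential(rate 1) | t^(1/2) |
| S4 | Gamma(0.5, scale 1) | Gamma(0.5, scale 4) | numeric 1 − G(F⁻¹(1 − t)) |
| S5 | Normal(2, 1) | Gamma(2, scale 2) | numeric |
| S6 | Normal(1, 1) | Gamma(2, scale 2) | numeric |

Normal parameters are (mean, standard deviation); Gammas are
shape–scale, which is the parameterization under which the diseased group
is stochastically larger (AUC > 0.5), consistent with the marker
orientation — the rate parameterization would invert it.

`run_study` draws one sample per replicate and fits **all** requested
estimators to it (paired design), scoring each by the averaged squared
error `ASE = (1/N) Σ_j (ROĈ(t_j) − ROC(t_j))²`. By default the `t_j` are
the replicate's own operating-point FPRs (the empirical estimator
contributes its attained `TPR_j` at each point); this weights the steep,
data-dense part of the curve and is the convention under which the
benchmark values in the test suite hold. A fixed uniform grid
(`ASE_GRID`, 101 points on [0.005, 0.995], endpoints excluded because all
estimators interpolate them) can be passed instead, which weighs the
whole FPR axis evenly and yields systematically smaller ASE for steep
curves. Replicate r of scenario s at sizes (n1, n2) is seeded by
`SeedSequence([base_seed, crc32(s), n1, n2, r])`, so studies are
reproducible and estimators comparable replicate-by-replicate. Mean-ASE
confidence intervals use the percentile bootstrap (B = 1000); estimator
contrasts use two-sided paired t-tests on per-replicate ASE differences
(degenerate cases: identical vectors give p = 1, zero-variance non-zero
differences give the p → 0 limit).

What the generator emulates: independent random sampling from known
smooth marker distributions with continuous values (ties occur with
probability zero). What it does not: measurement rounding and heavy
tying, covariates, verification bias, clustered or paired designs —
passing tests therefore say nothing about those features of real data.
A kernel-smoothed comparator is not included; external estimators can be
attached to the benchmark with `register_estimator`.

## Problem sizes

The packaged Monte Carlo checks use 200 paired replicates per scenario at
(n1, n2) = (100, 100), and 500 replicates for the empirical-only cell at
(125, 75); at these sizes the Monte Carlo standard error of a mean ASE is
around 2–4 % of its value, comfortably inside the comparison tolerances.
The full 9-size × 6-scenario × 8-estimator grid at 1000 replicates is
available through `nurbsroc simulate` for users who want it.

## Numerical choices

* Basis evaluation builds the full lower-degree triangle of the
  recursion (the top-level functions reference one extra lower-degree
  neighbour), vectorised over evaluation points.
* Quantile convention: `ecdf_quantile(v, p) = inf{x : F_n(x) ≥ p}` for
  p > 0, `min(v)` at p = 0.
* Control points from a genuine empirical ROC are automatically
  non-decreasing; if a user-supplied curve violates monotonicity they are
  projected by isotonic regression (pool-adjacent-violators) and flagged.
* Degenerate inputs: n1 = n2 = 1 fits and returns a valid monotone curve
  through (0,0) and (1,1); samples with too few distinct values fall
  back to zero interior knots.
* AUC: exact step-function area for the empirical curve; 1001-point
  trapezoid for smooth curves (error well below the third decimal).
* Serialization: model JSON carries degree, interior knots, weights,
  control abscissae/values, AIC and objective, and round-trips exactly;
  CSV floats use 17 significant digits and are re-read with
  correctly-rounded parsing.

## Known limitations

* Monotonicity of the fitted rational curve is verified empirically, not
  guaranteed analytically; no projection is applied to the fitted curve.
* The weight optimization is non-convex; L-BFGS-B from the equal-weight
  start can in principle stop at a local minimum (tests bound it against
  a brute-force grid on small problems).
* AIC-based knot counts are variable between nearby samples; the fitted
  curves are nonetheless stable, which is what the ASE measures.
* No asymptotic variance theory is provided; uncertainty comes from the
  bootstrap.
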