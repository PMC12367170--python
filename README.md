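# nurbsroc

Nonparametric ROC curve estimation with non-uniform rational B-splines
(NURBS), for biostatisticians and epidemiologists evaluating continuous
diagnostic markers.

## The problem and the estimator

Given marker values for a healthy group `X_1, ..., X_n1` (distribution
function `F`) and a diseased group `Y_1, ..., Y_n2` (distribution
function `G`), with larger values indicating disease, the ROC curve is

    ROC(t) = 1 − G(F⁻¹(1 − t)),   t ∈ [0, 1].

The plug-in empirical estimator `ROCₙ(t) = 1 − G_{n2}(F_{n1}⁻¹(1 − t))`
is consistent but jagged; Bernstein-polynomial smoothing is smooth but
rigid. This package implements a rational B-spline smoother that keeps
the best of both:

    ROĈ(t) = Σₖ ROCₙ(θₖ) · wₖ N_{k,m}(t) / Σⱼ wⱼ N_{j,m}(t)

where `N_{k,m}` are degree-`m` B-spline basis functions on a clamped knot
vector (Cox–de Boor recursion), `θₖ = (1/m) Σᵢ t_{i+k}` are the averaged
knot positions, the control values are the empirical ROC at `θₖ`, and the
weights `wₖ ≥ 10⁻⁶` are fitted by bounded least squares (L-BFGS-B)
against the empirical curve's operating points. Interior knots sit at
equally spaced percentiles of the observed false-positive rates; their
number is chosen by minimising

    AIC = log(MSE) + 2(m + l)/N .

With no interior knots and equal weights the estimator reduces exactly to
the Bernstein-polynomial ROC estimator. The fitted curve interpolates
(0, 0) and (1, 1) by construction.

## Worked example

```python
import numpy as np
from nurbsroc import NURBSROC

rng = np.random.default_rng(0)
x = rng.normal(0.0, 1.0, 100)   # healthy
y = rng.normal(2.0, 1.2, 100)   # diseased

res = NURBSROC(x, y, degree=6).fit()
print(res.summary())
```

prints

```
NURBS ROC estimation results
==============================================
degree (m):            6
interior knots (l-1):  1
control points (m+l):  8
least-squares obj.:    4.06096
AIC:                   -3.82228
AUC (trapezoid):       0.8840
optimizer converged:   True
n1, n2:                100, 100
empirical AUC:         0.8855
==============================================
```

One interior knot was selected by AIC; the fitted smooth curve has AUC
0.884, close to the empirical (Mann–Whitney) AUC 0.886 — here the true
AUC is Φ(2/√(1+1.2²)) ≈ 0.900. (The least-squares objective is a sum
over the curve's ~201 operating points, not a mean.) `res.predict(t)` evaluates the curve,
`res.conf_band(B=1000, level=0.95)` gives pointwise bootstrap bands, and
`res.to_json()` serialises the model.

The same fit from the shell, reading a CSV with `value` and `status`
(0 = healthy, 1 = diseased) columns:

```sh
nurbsroc fit markers.csv --degree 6 --bootstrap 1000 --seed 1 --out run
# -> run.curve.csv (t, roc_hat, lower, upper), run.model.json, run.report.json
```

`nurbsroc simulate` runs paired Monte Carlo comparisons of the empirical,
Bernstein (`bp2/bp4/bp6`), NURBS (`nb2/nb4/nb6`) and adaptive-degree
(`m = 0.5·n2^(2/3)`) estimators under six built-in scenarios S1–S6
(normal, exponential and gamma group pairs with known true ROC curves),
scoring each fit by the averaged squared error (ASE) against the truth.

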