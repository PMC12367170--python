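import itertools
import math

import numpy as np
import pytest

from nurbsroc import (
    BernsteinROC,
    FitConfig,
    NURBSROC,
    NURBSROCResults,
    Sample,
    adaptive_degree,
    aic_score,
    bspline_basis_matrix,
    build_knot_vector,
    control_points,
    empirical_roc,
    fit_weights,
    greville_abscissae,
    select_knots_aic,
)
from nurbsroc.empirical import EmpiricalROC


def make_results(kv, p, w, emp=None):
    return NURBSROCResults(
        kv=kv,
        control_abscissae=greville_abscissae(kv),
        control_values=np.asarray(p, float),
        weights=np.asarray(w, float),
        objective=0.0,
        emp=emp,
    )


def diagonal_emp(n=10):
    """An EmpiricalROC whose curve and operating points are the diagonal."""
    g = np.arange(n + 1) / n
    return EmpiricalROC(g, g, n, n, g, g)


class TestControlPoints:
    def test_separated(self, separated_sample):
        emp = empirical_roc(separated_sample)
        p, adjusted = control_points(emp, build_knot_vector(2, ()))
        assert np.allclose(p, [0.0, 1.0, 1.0])
        assert not adjusted

    def test_diagonal_curve(self):
        p, _ = control_points(diagonal_emp(10), build_knot_vector(2, ()))
        assert np.allclose(p, [0.0, 0.5, 1.0])

    def test_always_monotone_with_endpoints(self, rng):
        for _ in range(10):
            emp = empirical_roc(Sample(rng.normal(size=11), rng.normal(1, 1, size=7)))
            kv = build_knot_vector(int(rng.integers(1, 7)), ())
            p, _ = control_points(emp, kv)
            assert p[0] == 0.0 and p[-1] == 1.0
            assert np.all(np.diff(p) >= 0)

    def test_isotonic_projection_of_pathological_curve(self):
        # hand-built non-monotone "curve": projection kicks in and flags it
        g = np.array([0.0, 0.25, 0.5, 0.75, 1.0])
        vals = np.array([0.0, 0.6, 0.3, 0.9, 1.0])
        emp = EmpiricalROC(g, vals, 4, 4, g, vals)
        p, adjusted = control_points(emp, build_knot_vector(2, (0.5, 0.7)))
        assert adjusted
        assert np.all(np.diff(p) >= 0)


class TestEvaluate:
    def test_linear_precision_model(self, rng):
        kv = build_knot_vector(3, (0.3, 0.7))
        theta = greville_abscissae(kv)
        res = make_results(kv, theta, np.ones(kv.n_basis))
        t = np.linspace(0, 1, 101)
        assert np.max(np.abs(res(t) - t)) < 1e-12

    def test_hand_bernstein_value(self):
        kv = build_knot_vector(2, ())
        res = make_results(kv, [0.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert res(0.5) == pytest.approx(0.75, abs=1e-15)

    def test_endpoint_interpolation(self, rng):
        for _ in range(5):
            sample = Sample(rng.normal(size=15), rng.normal(1, 1, size=15))
            res = NURBSROC(sample=sample, degree=4).fit()
            assert res(0.0) == 0.0
            assert res(1.0) == 1.0

    def test_domain_error(self):
        kv = build_knot_vector(2, ())
        res = make_results(kv, [0, 0.5, 1], [1, 1, 1])
        with pytest.raises(ValueError):
            res(-0.1)


class TestFitWeights:
    def test_zero_residual_fixed_point(self):
        emp = diagonal_emp(12)
        kv = build_knot_vector(3, (0.5,))
        p, _ = control_points(emp, kv)
        w, obj, info = fit_weights(emp, kv, p)
        # the equal-weight spline already reproduces the diagonal exactly
        assert obj <= info["start_objective"] + 1e-15
        assert info["start_objective"] < 1e-20
        t = np.linspace(0, 1, 51)
        res = make_results(kv, p, w)
        assert np.max(np.abs(res(t) - t)) < 1e-8

    def test_brute_force_grid_oracle(self, tiny_sample):
        emp = empirical_roc(tiny_sample)
        kv = build_knot_vector(2, ())
        p, _ = control_points(emp, kv)
        w, obj, _ = fit_weights(emp, kv, p)

        basis = bspline_basis_matrix(kv, emp.fpr_points)
        target = emp.tpr_points
        grid1d = np.arange(0.05, 3.0001, 0.05)
        combos = np.array(list(itertools.product(grid1d, repeat=3)))
        denom = basis @ combos.T
        numer = (basis * p) @ combos.T
        objs = ((target[:, None] - numer / denom) ** 2).sum(axis=0)
        assert obj <= objs.min() + 1e-8

    def test_objective_never_worse_than_equal_weights(self, rng):
        for _ in range(5):
            emp = empirical_roc(Sample(rng.normal(size=20), rng.normal(1.5, 1, size=20)))
            kv = build_knot_vector(4, (0.5,))
            p, _ = control_points(emp, kv)
            _, obj, info = fit_weights(emp, kv, p)
            assert obj <= info["start_objective"] + 1e-12

    def test_start_scale_invariance(self, tiny_sample):
        emp = empirical_roc(tiny_sample)
        kv = build_knot_vector(2, ())
        p, _ = control_points(emp, kv)
        t = np.linspace(0, 1, 101)
        ref_w, ref_obj, _ = fit_weights(emp, kv, p)
        ref_curve = make_results(kv, p, ref_w)(t)
        for c in (0.5, 2.0):
            w, obj, _ = fit_weights(emp, kv, p, start=np.full(3, c))
            curve = make_results(kv, p, w)(t)
            assert np.max(np.abs(curve - ref_curve)) < 1e-4
            assert obj == pytest.approx(ref_obj, abs=1e-8)


class _CurveStub:
    """Evaluable curve with a fixed control-point count, for AIC arithmetic."""

    def __init__(self, offset, n_control):
        self.offset = offset
        self.n_control = n_control

    def __call__(self, t):
        return np.asarray(t, float) + self.offset


class TestAicScore:
    def test_hand_arithmetic(self):
        # MSE 0.01 with m=4, l=1 (5 control points) over N=100 points
        emp = diagonal_emp(10)
        grid = np.linspace(0, 1, 100)
        score = aic_score(emp, _CurveStub(0.1, 5), grid, target=grid)
        assert score == pytest.approx(math.log(0.01) + 10 / 100, abs=1e-12)

    def test_penalty_arithmetic(self):
        emp = diagonal_emp(10)
        grid = np.linspace(0, 1, 50)
        a = aic_score(emp, _CurveStub(0.1, 5), grid, target=grid)
        b = aic_score(emp, _CurveStub(0.1, 6), grid, target=grid)
        assert b - a == pytest.approx(2.0 / 50, abs=1e-12)

    def test_perfect_fit_is_floored_and_smallest(self):
        emp = diagonal_emp(10)
        grid = np.linspace(0, 1, 50)
        perfect = aic_score(emp, _CurveStub(0.0, 5), grid, target=grid)
        assert np.isfinite(perfect)
        assert perfect < aic_score(emp, _CurveStub(1e-6, 5), grid, target=grid)


class TestKnotSelection:
    def test_argmin_against_independent_recomputation(self, tiny_sample):
        emp = empirical_roc(tiny_sample)
        m = 2
        cfg = FitConfig(degree=m, max_interior=2)
        chosen = select_knots_aic(emp, m, cfg)

        # step-by-step recomputation of every candidate score
        scores = {}
        grid, target = emp.fpr_points, emp.tpr_points
        for n_int in range(0, 3):
            if n_int == 0:
                interior = ()
            else:
                l = n_int + 1
                interior = np.quantile(grid, np.arange(1, l) / l)
                if np.any(interior <= 0) or np.any(interior >= 1) or np.any(np.diff(interior) <= 0):
                    continue
            kv = build_knot_vector(m, interior)
            p, _ = control_points(emp, kv)
            w, obj, _ = fit_weights(emp, kv, p)
            mse = max(obj / grid.size, 1e-300)
            scores[n_int] = math.log(mse) + 2 * kv.n_basis / grid.size
        best = min(scores, key=lambda k: (scores[k], k))
        assert chosen.n_interior == best
        assert chosen.aic == pytest.approx(scores[best], abs=1e-9)
        assert all(chosen.aic <= s + 1e-12 for s in scores.values())

    def test_separated_sample_near_zero_residual(self, separated_sample):
        emp = empirical_roc(separated_sample)
        res = select_knots_aic(emp, 2, FitConfig(degree=2))
        assert res.aic == min(s for _, s in res.aic_trace)
        assert res.objective <= res.optimizer_info["start_objective"] + 1e-12

    def test_degenerate_candidates_are_skipped(self):
        # two distinct pooled values: every quantile knot collapses to the
        # boundary of (0,1), so only l-1 = 0 remains
        emp = empirical_roc(Sample([1.0, 1.0, 1.0], [2.0, 2.0]))
        res = select_knots_aic(emp, 1, FitConfig(degree=1, max_interior=3))
        assert res.n_interior == 0


class TestFitPipeline:
    def test_smoke_degenerate_sizes(self):
        res = NURBSROC([1.0], [2.0], degree=3).fit()
        t = np.linspace(0, 1, 101)
        vals = res(t)
        assert res(0.0) == 0.0 and res(1.0) == 1.0
        assert np.all(np.diff(vals) >= -1e-12)

    def test_identical_samples_near_diagonal(self):
        v = np.arange(1.0, 21.0)
        res = NURBSROC(v, v, degree=2).fit()
        t = np.linspace(0, 1, 201)
        assert np.max(np.abs(res(t) - t)) < 0.05

    def test_beats_empirical_on_binormal_draws(self):
        """Smoothing should beat the raw step curve on most replicates."""
        import nurbsroc

        st = nurbsroc.run_study(["S1"], [(100, 100)], 50, ["empirical", "nb6"], base_seed=11)
        wide = st.data.pivot_table(index="replicate", columns="estimator", values="ase")
        assert (wide["nb6"] < wide["empirical"]).mean() >= 0.9

    def test_fitted_monotone_on_fine_grid(self, rng):
        t = np.linspace(0, 1, 512)
        for _ in range(8):
            sample = Sample(rng.normal(size=40), rng.normal(1.2, 1, size=40))
            res = NURBSROC(sample=sample, degree=5).fit()
            vals = res(t)
            assert np.all(np.diff(vals) >= -1e-8)
            assert np.all((vals >= -1e-12) & (vals <= 1 + 1e-12))

    def test_flip_option(self, rng):
        x = rng.normal(size=30)
        y = rng.normal(-1.5, 1, size=30)  # negative predictor
        res = NURBSROC(x, y, degree=4, flip=True).fit()
        assert res.auc() > 0.5

    def test_summary_mentions_key_fields(self, tiny_sample):
        res = NURBSROC(sample=tiny_sample, degree=2).fit()
        text = res.summary()
        assert "AIC" in text and "AUC" in text and "interior knots" in text


class TestAdaptiveDegree:
    @pytest.mark.parametrize("n2,expected", [(100, 11), (1, 1), (8, 2), (75, 9)])
    def test_examples(self, n2, expected):
        assert adaptive_degree(n2) == expected

    def test_model_uses_rule(self, rng):
        sample = Sample(rng.normal(size=10), rng.normal(1, 1, size=8))
        model = NURBSROC(sample=sample, adaptive=True, degree=None)
        assert model.degree == adaptive_degree(8) == 2


class TestBernstein:
    def test_direct_sum_oracle(self, rng):
        sample = Sample(rng.normal(size=12), rng.normal(1, 1, size=9))
        emp = empirical_roc(sample)
        res = BernsteinROC(sample=sample, degree=4).fit()
        t = 0.5
        expected = sum(
            emp(k / 4) * math.comb(4, k) * t**k * (1 - t) ** (4 - k) for k in range(5)
        )
        assert res(t) == pytest.approx(expected, abs=1e-12)

    def test_separated_closed_form(self, separated_sample):
        res = BernsteinROC(sample=separated_sample, degree=2).fit()
        t = np.linspace(0, 1, 101)
        assert np.max(np.abs(res(t) - (2 * t - t**2))) < 1e-12

    def test_reduction_from_equal_weight_nurbs(self, rng):
        sample = Sample(rng.normal(size=15), rng.normal(1, 1, size=15))
        bern = BernsteinROC(sample=sample, degree=5).fit()
        emp = empirical_roc(sample)
        kv = build_knot_vector(5, ())
        p, _ = control_points(emp, kv)
        nurbs_equal = make_results(kv, p, np.ones(kv.n_basis))
        t = np.linspace(0, 1, 257)
        assert np.max(np.abs(bern(t) - nurbs_equal(t))) < 1e-12


class TestSerialization:
    def test_json_round_trip(self, tiny_sample):
        res = NURBSROC(sample=tiny_sample, degree=3).fit()
        restored = NURBSROCResults.from_json(res.to_json())
        assert restored.degree == res.degree
        assert np.array_equal(restored.weights, res.weights)
        assert np.array_equal(restored.control_values, res.control_values)
        assert restored.aic == res.aic and restored.objective == res.objective
        t = np.linspace(0, 1, 101)
        assert np.array_equal(restored(t), res(t))


class TestBootstrapBand:
    def test_seeded_determinism(self, tiny_sample):
        res = NURBSROC(sample=tiny_sample, degree=2).fit()
        g1, lo1, hi1 = res.conf_band(B=50, seed=3)
        g2, lo2, hi2 = res.conf_band(B=50, seed=3)
        assert np.array_equal(lo1, lo2) and np.array_equal(hi1, hi2)

    def test_nesting_and_order(self, tiny_sample):
        res = NURBSROC(sample=tiny_sample, degree=2).fit()
        _, lo95, hi95 = res.conf_band(B=60, level=0.95, seed=4)
        _, lo50, hi50 = res.conf_band(B=60, level=0.50, seed=4)
        assert np.all(lo95 <= lo50 + 1e-12) and np.all(hi50 <= hi95 + 1e-12)
        assert np.all(lo95 <= hi95)

    def test_separated_sample_band_high(self, separated_sample):
        res = NURBSROC(sample=separated_sample, degree=2).fit()
        grid = np.linspace(0, 1, 21)
        _, lo, hi = res.conf_band(B=30, grid=grid, seed=5)
        # every resample stays perfectly separated
        assert lo[grid >= 0.5].min() >= 0.5
        assert np.all(hi <= 1.0 + 1e-12)

    def test_validation(self, tiny_sample):
        res = NURBSROC(sample=tiny_sample, degree=2).fit()
        with pytest.raises(ValueError):
            res.conf_band(B=1)
        with pytest.raises(ValueError):
            res.conf_band(B=10, level=1.5)
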