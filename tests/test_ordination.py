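"""nMDS, PAVA, PERMANOVA, axis-time regression and fixed-df smooths."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from sklearn.isotonic import IsotonicRegression

import gutdyn as gd
from gutdyn.ordination import _classical_scaling, _disparities, _stress1
from oracles import permanova_exact_p, permanova_sums


class TestIsotonicFit:
    def test_hand_pooling(self):
        np.testing.assert_allclose(gd.isotonic_fit([1, 3, 2]), [1, 2.5, 2.5])

    def test_identity_cases(self):
        np.testing.assert_array_equal(gd.isotonic_fit([1, 2, 3]), [1, 2, 3])
        np.testing.assert_array_equal(gd.isotonic_fit([2.0, 2.0, 2.0]), [2, 2, 2])

    def test_empty_input(self):
        with pytest.raises(ValueError, match="empty"):
            gd.isotonic_fit([])

    def test_matches_sklearn_on_random_instances(self, rng):
        iso = IsotonicRegression()
        for _ in range(25):
            y = rng.normal(size=30)
            w = rng.uniform(0.5, 2.0, size=30)
            mine = gd.isotonic_fit(y, w)
            ref = iso.fit_transform(np.arange(30), y, sample_weight=w)
            np.testing.assert_allclose(mine, ref, atol=1e-9)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.lists(st.floats(-50, 50), min_size=1, max_size=25))
    def test_monotone_and_mean_preserving(self, y):
        fit = gd.isotonic_fit(y)
        assert np.all(np.diff(fit) >= -1e-12)
        assert np.mean(fit) == pytest.approx(np.mean(y), abs=1e-9)


def _embeddable_distances(rng, n=5, k=2):
    pts = rng.normal(size=(n, k))
    return DistanceMatrix(squareform(pdist(pts)), ids=[f"s{i}" for i in range(n)])


class TestNmds:
    def test_embeddable_configuration_reaches_tiny_stress(self, rng):
        d = _embeddable_distances(rng)
        res = gd.nmds(d, k=2, seed=0)
        assert res.stress < 1e-3

    def test_stress_not_above_classical_start(self, rng):
        pts = rng.normal(size=(9, 4))
        d = DistanceMatrix(squareform(pdist(pts)), ids=[f"s{i}" for i in range(9)])
        res = gd.nmds(d, k=2, seed=0)
        X0 = _classical_scaling(np.asarray(d.data), 2, np.random.default_rng(0))
        d0 = pdist(X0)
        delta = squareform(np.asarray(d.data), checks=False)
        s0 = _stress1(d0, _disparities(d0, delta))
        assert res.stress <= s0 + 1e-12

    def test_rank_invariance_under_monotone_transform(self, rng):
        pts = rng.normal(size=(10, 3))
        D = squareform(pdist(pts))
        ids = [f"s{i}" for i in range(10)]
        s1 = gd.nmds(DistanceMatrix(D, ids=ids), seed=0).stress
        s2 = gd.nmds(DistanceMatrix(D**2, ids=ids), seed=0).stress
        assert abs(s1 - s2) < 0.02

    def test_stress_invariant_under_orthogonal_maps(self, rng):
        d = _embeddable_distances(rng, n=8)
        res = gd.nmds(d, k=2, seed=0)
        X = res.coordinates.to_numpy()
        delta = squareform(np.asarray(d.data), checks=False)
        q, _ = np.linalg.qr(rng.normal(size=(2, 2)))
        for Y in (X, X @ q, 3.0 * X):
            dcfg = pdist(Y)
            scale_free = _stress1(dcfg, _disparities(dcfg, delta))
            assert scale_free == pytest.approx(res.stress, abs=1e-9)

    def test_coordinates_centered_and_axis_order(self, rng):
        d = _embeddable_distances(rng, n=12, k=3)
        res = gd.nmds(d, k=2, seed=3)
        X = res.coordinates.to_numpy()
        np.testing.assert_allclose(X.mean(axis=0), 0.0, atol=1e-9)
        assert X[:, 0].var() >= X[:, 1].var()

    def test_degenerate_inputs(self):
        ids = list("abcd")
        with pytest.raises(ValueError, match="all zeros"):
            gd.nmds(DistanceMatrix(np.zeros((4, 4)), ids=ids))


class TestPermanova:
    @staticmethod
    def _toy():
        d = np.array(
            [[0, 1, 2, 2], [1, 0, 2, 2], [2, 2, 0, 1], [2, 2, 1, 0]], dtype=float
        )
        return DistanceMatrix(d, ids=list("abcd")), ["g1", "g1", "g2", "g2"]

    def test_hand_worked_toy(self):
        dm, groups = self._toy()
        res = gd.permanova(dm, groups, n_permutations=99, seed=0)
        assert res.pseudo_f == pytest.approx(7.0)
        assert res.r_squared == pytest.approx(3.5 / 4.5)
        assert res.p_value >= 1.0 / 100

    def test_f_invariant_under_group_renaming(self):
        dm, groups = self._toy()
        renamed = ["beta" if g == "g1" else "alpha" for g in groups]
        a = gd.permanova(dm, groups, n_permutations=49, seed=1)
        b = gd.permanova(dm, renamed, n_permutations=49, seed=1)
        assert a.pseudo_f == b.pseudo_f
        assert a.r_squared == b.r_squared

    def test_exchangeable_null_is_not_significant(self):
        d = np.ones((8, 8)) - np.eye(8)
        dm = DistanceMatrix(d, ids=[f"s{i}" for i in range(8)])
        res = gd.permanova(dm, ["a"] * 4 + ["b"] * 4, n_permutations=199, seed=0)
        assert res.p_value > 0.5

    def test_matches_sum_definition_oracle(self, rng):
        for _ in range(20):
            pts = rng.normal(size=(9, 3))
            D = squareform(pdist(pts))
            labels = rng.permutation(["a"] * 3 + ["b"] * 3 + ["c"] * 3)
            res = gd.permanova(
                DistanceMatrix(D, ids=[f"s{i}" for i in range(9)]),
                labels,
                n_permutations=9,
                seed=0,
            )
            f_ref, r2_ref = permanova_sums(D, labels)
            assert res.pseudo_f == pytest.approx(f_ref, abs=1e-9)
            assert res.r_squared == pytest.approx(r2_ref, abs=1e-12)

    def test_monte_carlo_agrees_with_full_enumeration(self, rng):
        pts = rng.normal(size=(6, 2))
        pts[:3] += 1.5
        D = squareform(pdist(pts))
        labels = ["a", "a", "a", "b", "b", "b"]
        p_exact = permanova_exact_p(D, labels)
        res = gd.permanova(
            DistanceMatrix(D, ids=[f"s{i}" for i in range(6)]),
            labels,
            n_permutations=10000,
            seed=42,
        )
        se = np.sqrt(p_exact * (1 - p_exact) / 10000)
        assert abs(res.p_value - p_exact) <= 2 * se + 2e-4

    def test_errors(self):
        dm, _ = self._toy()
        with pytest.raises(ValueError, match="size 1"):
            gd.permanova(dm, ["a", "a", "a", "b"])
        d3 = DistanceMatrix(np.ones((3, 3)) - np.eye(3), ids=list("abc"))
        with pytest.raises(ValueError, match="4"):
            gd.permanova(d3, ["a", "b", "b"])


class TestAxisTimeRegression:
    def _result_from_axis(self, axis):
        coords = pd.DataFrame(
            {"axis1": axis, "axis2": np.zeros(len(axis))},
            index=[f"s{i}" for i in range(len(axis))],
        )
        return gd.NmdsResult(coordinates=coords, stress=0.1, n_iterations=5, converged=True)

    def test_perfect_linear_fit(self):
        days = np.arange(30)
        res = self._result_from_axis(0.3 * days - 2)
        fit = gd.axis_time_regression(res, days)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.slope == pytest.approx(0.3)

    def test_independent_noise_has_no_signal(self, rng):
        days = np.arange(200)
        fit = gd.axis_time_regression(self._result_from_axis(rng.normal(size=200)), days)
        assert fit.r_squared < 0.05

    def test_duplicated_points_equal_weighted_fit(self, rng):
        days = rng.integers(1, 50, size=40)
        axis = 0.1 * days + rng.normal(scale=0.5, size=40)
        doubled_days = np.concatenate([days, days])
        doubled_axis = np.concatenate([axis, axis])
        a = gd.axis_time_regression(self._result_from_axis(doubled_axis), doubled_days)
        import statsmodels.api as sm

        X = sm.add_constant(days.astype(float))
        ref = sm.WLS(axis, X, weights=np.full(40, 2.0)).fit()
        assert a.slope == pytest.approx(ref.params[1], abs=1e-9)
        assert a.intercept == pytest.approx(ref.params[0], abs=1e-9)

    def test_constant_days_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            gd.axis_time_regression(self._result_from_axis(np.arange(5.0)), np.ones(5))


class TestSmoothFit:
    def test_exact_on_cubic_polynomial(self, rng):
        x = np.linspace(1, 365, 120)
        y = 1e-6 * x**3 - 2e-4 * x**2 + 0.01 * x - 1
        for df in (4, 9):
            fit = gd.smooth_fit(x, y, df=df)
            assert fit.r_squared == pytest.approx(1.0, abs=1e-9)
            np.testing.assert_allclose(fit.fitted, y, atol=1e-8)

    def test_constant_response_flat_derivative(self):
        x = np.linspace(0, 10, 50)
        fit = gd.smooth_fit(x, np.full(50, 3.0), df=5)
        np.testing.assert_allclose(fit.derivative, 0.0, atol=1e-9)

    def test_sinusoid_recovery(self, rng):
        x = np.arange(1, 366, dtype=float)
        y = np.sin(x / 30.0) + rng.normal(scale=0.05, size=365)
        fit = gd.smooth_fit(x, y, df=9)
        assert fit.r_squared > 0.95

    def test_bands_contain_fit_and_widen_in_gaps(self, rng):
        x = np.concatenate([np.linspace(0, 4, 60), [5.5, 6.5], np.linspace(8, 12, 60)])
        y = np.sin(x) + rng.normal(scale=0.1, size=122)
        fit = gd.smooth_fit(x, y, df=6)
        assert (fit.lower95 <= fit.fitted + 1e-12).all()
        assert (fit.upper95 >= fit.fitted - 1e-12).all()
        width = fit.upper95 - fit.lower95
        gap_width = width[(fit.grid > 5.0) & (fit.grid < 7.0)].mean()
        dense_width = width[(fit.grid > 1.5) & (fit.grid < 2.5)].mean()
        assert gap_width > dense_width

    def test_too_few_distinct_x(self):
        with pytest.raises(ValueError, match="df"):
            gd.smooth_fit(np.array([1.0, 2, 3, 4, 5] * 4), np.zeros(20), df=9)
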