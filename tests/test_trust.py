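"""Stability measure, bootstrap G_mean CI, exact Shapley values, rankings."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from clintrust.cohort import Cohort, FeatureSpec
from clintrust.trust import (
    FeatureRanking,
    GmeanCI,
    Neighborhood,
    TrustReport,
    exact_shapley,
    global_stability,
    gmean_bootstrap_ci,
    instance_stability,
    rank_features,
    shapley_ranking,
    spearman_rho,
    trust_report,
)


class TestInstanceStability:
    def test_balanced_equidistant_neighborhood_is_zero(self):
        nb = Neighborhood(d_same=[1.0, 2.0], d_diff=[1.0, 2.0])
        assert instance_stability(nb) == 0.0

    def test_all_same_label_equidistant_k3(self):
        nb = Neighborhood(d_same=[3.0, 3.0, 3.0], d_diff=[])
        assert instance_stability(nb) == pytest.approx(math.exp(-0.5), abs=1e-12)

    def test_all_opposite_label_sign_symmetry(self):
        nb = Neighborhood(d_same=[], d_diff=[3.0, 3.0, 3.0])
        assert instance_stability(nb) == pytest.approx(-math.exp(-0.5), abs=1e-12)

    def test_zero_distance_duplicates_reach_endpoints(self):
        # all neighbors coincide with x: kernel weight 1, value exactly +-1
        assert instance_stability(Neighborhood([0.0, 0.0], [])) == 1.0
        assert instance_stability(Neighborhood([], [0.0, 0.0])) == -1.0

    def test_empty_neighborhood_rejected(self):
        with pytest.raises(ValueError):
            Neighborhood([], [])

    def test_from_points_matches_distance_construction(self):
        x = np.zeros(2)
        nb = Neighborhood.from_points(x, same=[[3, 4]], diff=[[0, 5], [5, 0]])
        np.testing.assert_allclose(nb.d_same, [5.0])
        np.testing.assert_allclose(nb.d_diff, [5.0, 5.0])
        assert instance_stability(nb) == pytest.approx(-1 / 3 * math.exp(-0.5))

    @given(
        st.lists(st.floats(min_value=0, max_value=1e3), max_size=20),
        st.lists(st.floats(min_value=0, max_value=1e3), max_size=20),
    )
    @settings(max_examples=300, deadline=None)
    def test_bounded_and_signed(self, d_same, d_diff):
        if not d_same and not d_diff:
            return
        v = instance_stability(Neighborhood(d_same, d_diff))
        assert -1.0 <= v <= 1.0
        if not d_diff:
            assert v > 0
        if not d_same:
            assert v < 0


def _brute_force_global(points, labels):
    """Independent literal evaluation of the stability formula."""
    points = np.asarray(points, dtype=float)
    out = []
    for i, x in enumerate(points):
        ds, dd = [], []
        for j, z in enumerate(points):
            if i == j:
                continue
            d = math.dist(x, z)
            (ds if labels[j] == labels[i] else dd).append(d)
        k = len(ds) + len(dd)
        sigma = (sum(ds) + sum(dd)) / k
        if sigma == 0:
            w = lambda d: 1.0
        else:
            w = lambda d: math.exp(-d * d / (2 * sigma * sigma))
        out.append((sum(w(d) for d in ds) - sum(w(d) for d in dd)) / k)
    return out


class TestGlobalStability:
    def _cohort(self, points):
        X = pd.DataFrame(np.asarray(points, dtype=float), columns=["u", "v"])
        return Cohort(X, np.zeros(len(X), dtype=int))

    def test_constant_label_model_all_positive(self):
        rng = np.random.default_rng(0)
        cohort = self._cohort(rng.normal(size=(15, 2)))
        res = global_stability(lambda X: np.ones(len(X), dtype=int), cohort)
        assert (res.per_instance > 0).all()
        assert res.global_value == pytest.approx(res.per_instance.mean())

    def test_matches_brute_force_on_two_cluster_configuration(self):
        pts = [[0, 0], [0.1, 0], [0, 0.1], [5, 5], [5.1, 5], [5, 5.1]]
        cohort = self._cohort(pts)
        predict = lambda X: (X["u"].to_numpy() > 2).astype(int)
        res = global_stability(predict, cohort, normalize=False)
        expected = _brute_force_global(pts, predict(cohort.X))
        np.testing.assert_allclose(res.per_instance, expected, atol=1e-12)
        # consistently labelled clusters: within-cluster kernel mass wins
        assert res.global_value > 0 and (res.per_instance > 0).all()

    def test_duplicated_cohort_preserves_ordering(self):
        pts = [[0, 0], [1, 0], [3, 1], [0, 2]]
        predict = lambda X: (X["u"].to_numpy() >= 1).astype(int)
        single = global_stability(predict, self._cohort(pts), normalize=False)
        doubled = global_stability(predict, self._cohort(pts + pts), normalize=False)
        base = doubled.per_instance[:4]
        expected = _brute_force_global(pts + pts, predict(self._cohort(pts + pts).X))
        np.testing.assert_allclose(doubled.per_instance, expected, atol=1e-12)
        assert np.array_equal(np.argsort(single.per_instance), np.argsort(base))

    def test_single_instance_rejected(self):
        with pytest.raises(ValueError):
            global_stability(lambda X: np.zeros(len(X)), self._cohort([[0, 0]]))


class TestBootstrapCI:
    def test_perfect_predictions_degenerate_at_one(self):
        y = np.array([0] * 40 + [1] * 10)
        ci = gmean_bootstrap_ci(y, y, B=200, seed=0)
        assert (ci.lower, ci.upper) == (1.0, 1.0)

    def test_all_positive_predictor_degenerate_at_zero(self):
        y = np.array([0] * 40 + [1] * 10)
        ci = gmean_bootstrap_ci(y, np.ones_like(y), B=200, seed=0)
        assert (ci.lower, ci.upper) == (0.0, 0.0)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, 100)
        pred = np.where(rng.random(100) < 0.8, y, 1 - y)
        a = gmean_bootstrap_ci(y, pred, B=300, seed=42)
        b = gmean_bootstrap_ci(y, pred, B=300, seed=42)
        assert (a.lower, a.upper) == (b.lower, b.upper)

    def test_width_shrinks_with_sample_size(self):
        widths = {}
        for n in (50, 500):
            rng = np.random.default_rng(9)
            y = np.array(([0] * 9 + [1]) * (n // 10))
            pred = np.where(rng.random(n) < 0.85, y, 1 - y)
            widths[n] = gmean_bootstrap_ci(y, pred, B=2000, seed=7).width
        assert widths[500] < widths[50]

    def test_single_class_truth_rejected(self):
        with pytest.raises(ValueError):
            gmean_bootstrap_ci([1, 1, 1], [1, 0, 1], B=100, seed=0)

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            GmeanCI(0.8, 0.4, 200, 0.05)


def _oracle_permutation_shapley(predict, x, background, features):
    """Average marginal contribution over all M! feature orderings.

    Coalition value: mean model output with in-coalition features pinned
    to x and the rest taken from background rows (interventional).
    """
    M = len(features)
    bg = background[features].to_numpy(dtype=float)

    def value(coalition):
        rows = np.repeat(bg.copy(), 1, axis=0)
        for j in coalition:
            rows[:, j] = x[features[j]]
        return float(np.mean(predict(pd.DataFrame(rows, columns=features))))

    phi = np.zeros(M)
    for order in itertools.permutations(range(M)):
        current: tuple = ()
        v_prev = value(current)
        for j in order:
            current = current + (j,)
            v_new = value(current)
            phi[j] += v_new - v_prev
            v_prev = v_new
    return phi / math.factorial(M)


class TestExactShapley:
    def test_additive_model_closed_form(self):
        predict = lambda X: 2 * X["x1"].to_numpy() - X["x2"].to_numpy()
        inst = pd.DataFrame({"x1": [3.0], "x2": [5.0]})
        bg = pd.DataFrame({"x1": [1.0], "x2": [1.0]})
        attr = exact_shapley(predict, inst, bg)
        np.testing.assert_allclose(attr.phi[0], [4.0, -4.0], atol=1e-9)
        assert attr.base_value == pytest.approx(1.0)

    def test_efficiency_symmetry_null_player(self):
        rng = np.random.default_rng(2)
        # f uses x1+x2 symmetrically and ignores x4 entirely
        predict = lambda X: (X["x1"] + X["x2"]).to_numpy() ** 2 + 3 * X["x3"].to_numpy()
        bg = pd.DataFrame(rng.normal(size=(20, 4)), columns=["x1", "x2", "x3", "x4"])
        bg["x2"] = bg["x1"]  # exchangeable background for the symmetric pair
        inst = pd.DataFrame([[1.5, 1.5, -0.3, 9.9]], columns=bg.columns)
        attr = exact_shapley(predict, inst, bg)
        phi = attr.phi[0]
        f_x = predict(inst)[0]
        assert phi.sum() + attr.base_value == pytest.approx(f_x, abs=1e-9)
        assert phi[0] == pytest.approx(phi[1], abs=1e-9)  # symmetric players
        assert phi[3] == pytest.approx(0.0, abs=1e-9)  # null player

    def test_constant_model_all_zero(self):
        predict = lambda X: np.full(len(X), 7.0)
        bg = pd.DataFrame(np.arange(6.0).reshape(3, 2), columns=["a", "b"])
        attr = exact_shapley(predict, bg.iloc[[0]], bg)
        np.testing.assert_allclose(attr.phi, 0.0, atol=1e-12)

    @pytest.mark.parametrize("M", [2, 3, 4, 5])
    def test_matches_permutation_enumeration_oracle(self, M):
        rng = np.random.default_rng(M)
        cols = [f"f{j}" for j in range(M)]
        W = rng.normal(size=(M, M))

        def predict(X):
            V = X[cols].to_numpy(dtype=float)
            return np.einsum("ni,ij,nj->n", V, W, V) + V.sum(axis=1)

        bg = pd.DataFrame(rng.normal(size=(8, M)), columns=cols)
        inst = pd.DataFrame(rng.normal(size=(1, M)), columns=cols)
        attr = exact_shapley(predict, inst, bg)
        oracle = _oracle_permutation_shapley(predict, inst.iloc[0], bg, cols)
        np.testing.assert_allclose(attr.phi[0], oracle, atol=1e-9)

    def test_feature_limit_enforced(self):
        cols = [f"f{j}" for j in range(16)]
        df = pd.DataFrame(np.zeros((2, 16)), columns=cols)
        with pytest.raises(ValueError, match="sampling"):
            exact_shapley(lambda X: np.zeros(len(X)), df, df)


class TestRankingAndRho:
    def test_rank_by_mean_absolute_phi(self):
        attr_phi = np.array([[3.0, -1.0, 2.0], [-3.0, 1.0, -2.0]])
        from clintrust.trust import ShapleyAttribution

        attr = ShapleyAttribution(attr_phi, 0.0, ("a", "b", "c"))
        assert rank_features(attr).ranks == {"a": 1.0, "b": 3.0, "c": 2.0}

    def test_ties_get_average_ranks(self):
        r = FeatureRanking.from_importances({"a": 1.0, "b": 1.0, "c": 1.0})
        assert r.ranks == {"a": 2.0, "b": 2.0, "c": 2.0}

    def test_identical_eight_feature_rankings_rho_one(self):
        ranks = {f"f{j}": float(j + 1) for j in range(8)}
        r = FeatureRanking(ranks)
        assert spearman_rho(r, r) == pytest.approx(1.0)

    def test_reversed_ranking_rho_minus_one(self):
        a = FeatureRanking({"w": 1, "x": 2, "y": 3, "z": 4})
        b = FeatureRanking({"w": 4, "x": 3, "y": 2, "z": 1})
        assert spearman_rho(a, b) == pytest.approx(-1.0)

    def test_closed_formula_small_example(self):
        a = FeatureRanking({"a": 1, "b": 2, "c": 3, "d": 4})
        b = FeatureRanking({"a": 1, "b": 2, "c": 4, "d": 3})
        # 1 - 6*2 / (4*15)
        assert spearman_rho(a, b) == pytest.approx(0.8)

    def test_mismatched_feature_sets_rejected(self):
        with pytest.raises(ValueError):
            spearman_rho(FeatureRanking({"a": 1}), FeatureRanking({"b": 1}))


class TestTrustReport:
    def test_report_self_reference_and_round_trip(self, tmp_path, acs_cohort):
        from clintrust.models import ModelSpec, build_model

        model = build_model(ModelSpec("grace", params={"threshold": 140}))
        model.fit(acs_cohort.X, acs_cohort.y)
        reference = shapley_ranking(model, acs_cohort, seed=0,
                                    n_instances=20, n_background=20)
        rep = trust_report(model, acs_cohort, reference, B=200, seed=0,
                           shap_instances=20, shap_background=20, name="grace")
        assert rep.spearman == pytest.approx(1.0)  # model vs its own ranking
        assert rep.gmean_ci.width == pytest.approx(
            rep.gmean_ci.upper - rep.gmean_ci.lower
        )
        path = tmp_path / "trust.json"
        rep.to_json(path)
        back = TrustReport.from_json(path)
        assert back.to_dict() == rep.to_dict()
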