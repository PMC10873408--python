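"""Coefficient scaling, fuzzy c-means, and cluster surfaces."""

import numpy as np
import pandas as pd
import pytest
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score

from nutrigeom.clustering import (
    FuzzyCMeans,
    assign_clusters,
    cluster_surface,
    fuzzy_cmeans,
    scale_coefficients,
)
from nutrigeom.design import make_grid
from nutrigeom.expression import NutrientCoefficients
from nutrigeom.surfaces import surface_extrema


def _oracle_fcm(X, centers, m=2.0, tol=1e-12, max_iter=2000):
    """Independent implementation of the classic membership/center updates."""
    X = np.asarray(X, dtype=float)
    prev = np.inf
    for _ in range(max_iter):
        d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        d2 = np.clip(d2, 1e-300, None)
        inv = d2 ** (-1.0 / (m - 1.0))
        u = inv / inv.sum(axis=1, keepdims=True)
        centers = (u.T**m @ X) / (u.T**m).sum(axis=1, keepdims=True)
        d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        obj = float(((u**m) * d2).sum())
        if abs(prev - obj) < tol:
            break
        prev = obj
    return centers, u, obj


class TestScaleCoefficients:
    def test_row_zscore(self):
        scaled, ids, dropped = scale_coefficients(np.array([[1.0, 2.0, 3.0]]))
        np.testing.assert_allclose(scaled, [[-1.0, 0.0, 1.0]])
        assert not dropped

    def test_degenerate_row_dropped_and_flagged(self):
        coeffs = [
            NutrientCoefficients("flat", 5.0, 5.0, 5.0),
            NutrientCoefficients("ok", 1.0, 2.0, 3.0),
        ]
        scaled, ids, dropped = scale_coefficients(coeffs)
        assert dropped == ["flat"] and ids == ["ok"]
        assert scaled.shape == (1, 3)

    def test_idempotent(self, rng):
        X = rng.normal(size=(20, 3))
        once, _, _ = scale_coefficients(X)
        twice, _, _ = scale_coefficients(once)
        np.testing.assert_allclose(once, twice, atol=1e-12)

    def test_per_coefficient_mode(self, rng):
        X = rng.normal(size=(30, 3)) * [1, 10, 100]
        scaled, _, _ = scale_coefficients(X, mode="per_coefficient")
        np.testing.assert_allclose(scaled.mean(axis=0), 0, atol=1e-12)
        np.testing.assert_allclose(scaled.std(axis=0, ddof=1), 1, atol=1e-12)


class TestFuzzyCMeans:
    def test_separated_clouds_recovered(self, rng):
        a = rng.normal(size=(40, 3)) * 0.1 + [5, 0, 0]
        b = rng.normal(size=(40, 3)) * 0.1 + [-5, 0, 0]
        X = np.vstack([a, b])
        est = FuzzyCMeans(n_clusters=2, random_state=0).fit(X)
        truth = [0] * 40 + [1] * 40
        assert adjusted_rand_score(truth, est.labels_) == 1.0

    def test_equidistant_point_membership_half(self):
        X = np.array([[0.0, 0.0], [2.0, 0.0], [1.0, 5.0]])
        est = FuzzyCMeans(n_clusters=2, random_state=1, max_iter=0).fit(X)
        # force symmetric centers, then query the midpoint
        est.cluster_centers_ = np.array([[0.0, 0.0], [2.0, 0.0]])
        u = est.soft_predict(np.array([[1.0, 0.0]]))
        np.testing.assert_allclose(u, [[0.5, 0.5]])

    def test_point_on_center_gets_full_membership(self):
        X = np.vstack(
            [np.zeros((5, 2)), np.ones((5, 2)) * 4, [[2.0, 2.0]]]
        )
        est = FuzzyCMeans(n_clusters=2, random_state=0).fit(X)
        u = est.soft_predict(est.cluster_centers_[:1])
        np.testing.assert_allclose(u, [[1.0, 0.0]], atol=1e-12)

    def test_matches_independent_oracle_on_8_points(self):
        # two tight groups of four; both implementations reach the optimum
        X = np.array(
            [
                [0.0, 0.1], [0.1, -0.1], [-0.1, 0.0], [0.05, 0.05],
                [4.0, 4.1], [4.1, 3.9], [3.9, 4.0], [4.05, 4.05],
            ]
        )
        est = FuzzyCMeans(n_clusters=2, random_state=3, tol=1e-13).fit(X)
        oracle_centers, oracle_u, oracle_obj = _oracle_fcm(
            X, centers=np.array([[0.0, 0.0], [4.0, 4.0]])
        )
        order = np.argsort(oracle_centers[:, 0])
        np.testing.assert_allclose(est.objective_, oracle_obj, atol=1e-6)
        np.testing.assert_allclose(
            est.cluster_centers_, oracle_centers[order], atol=1e-6
        )
        np.testing.assert_allclose(est.membership_, oracle_u[:, order], atol=1e-6)

    def test_membership_rows_sum_to_one(self, rng):
        X = rng.normal(size=(50, 3))
        est = FuzzyCMeans(n_clusters=4, random_state=0).fit(X)
        np.testing.assert_allclose(est.membership_.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(est.membership_ >= 0) and np.all(est.membership_ <= 1)

    def test_small_fuzzifier_approaches_kmeans(self, rng):
        a = rng.normal(size=(30, 2)) * 0.2 + [3, 0]
        b = rng.normal(size=(30, 2)) * 0.2 + [-3, 0]
        X = np.vstack([a, b])
        est = FuzzyCMeans(n_clusters=2, m=1.05, random_state=0).fit(X)
        km = KMeans(n_clusters=2, n_init=10, random_state=0).fit(X)
        assert adjusted_rand_score(km.labels_, est.labels_) == 1.0
        assert est.membership_.max(axis=1).min() > 0.99

    def test_objective_nonincreasing_in_debug_mode(self, rng):
        X = rng.normal(size=(60, 3))
        FuzzyCMeans(n_clusters=3, random_state=2, debug_checks=True).fit(X)

    def test_permuting_rows_permutes_outputs(self, rng):
        X = rng.normal(size=(30, 3))
        est = FuzzyCMeans(n_clusters=3, random_state=5).fit(X)
        perm = rng.permutation(30)
        est2 = FuzzyCMeans(n_clusters=3, random_state=5).fit(X[perm])
        # canonical center ordering makes memberships comparable
        np.testing.assert_allclose(
            est.membership_[perm], est2.membership_, atol=1e-6
        )

    def test_too_many_clusters_rejected(self, rng):
        with pytest.raises(ValueError):
            FuzzyCMeans(n_clusters=5).fit(rng.normal(size=(4, 2)))

    def test_bad_fuzzifier_rejected(self, rng):
        with pytest.raises(ValueError, match="m must be > 1"):
            FuzzyCMeans(n_clusters=2, m=1.0).fit(rng.normal(size=(10, 2)))


class TestAssignClusters:
    def test_argmax_assignment(self):
        model = fuzzy_cmeans(
            np.array([[0.0, 0], [0.1, 0], [5.0, 0], [5.1, 0], [2.0, 3.0]]),
            k=2,
            seed=0,
        )
        assigns = assign_clusters(model)
        u = model.membership
        np.testing.assert_array_equal(
            list(assigns.values()), np.argmax(u, axis=1)
        )

    def test_tie_breaks_to_lowest_index(self):
        from nutrigeom.clustering import _argmax_low_index

        labels, ties = _argmax_low_index(np.array([[0.5, 0.5], [0.2, 0.8]]))
        assert labels[0] == 0 and ties == 1


class TestClusterSurface:
    def test_fat_zscore_cluster_peaks_at_fat_vertex(self, design):
        pct = design.sample_percent_matrix()
        fat_z = (pct["fat_pct"] - pct["fat_pct"].mean()) / pct["fat_pct"].std(ddof=1)
        values = pd.DataFrame(
            [fat_z.to_numpy()] * 4,
            index=[f"f{i}" for i in range(4)],
            columns=design.sample_ids,
        )
        surfs = cluster_surface(
            {f"f{i}": 0 for i in range(4)}, values, design, make_grid(resolution=10)
        )
        ex = surface_extrema(surfs[0])
        assert ex.argmax[:2] == (0.0, 0.0)  # the pure-fat origin

    def test_noise_cluster_selects_null_flat_surface(self, design, rng):
        values = pd.DataFrame(
            rng.normal(size=(6, 57)) * 0.1,
            index=[f"f{i}" for i in range(6)],
            columns=design.sample_ids,
        )
        surfs = cluster_surface(
            {f"f{i}": 0 for i in range(6)}, values, design, make_grid(resolution=10)
        )
        assert surfs[0].source_fit.order == "null"
        assert surface_extrema(surfs[0]).degenerate

    def test_carb_up_protein_down_gradient(self, design):
        pct = design.sample_percent_matrix()
        grad = pct["carb_pct"] - pct["protein_pct"]
        grad = (grad - grad.mean()) / grad.std(ddof=1)
        values = pd.DataFrame(
            [grad.to_numpy()] * 3,
            index=[f"f{i}" for i in range(3)],
            columns=design.sample_ids,
        )
        surfs = cluster_surface(
            {f"f{i}": 0 for i in range(3)}, values, design, make_grid(resolution=10)
        )
        ex = surface_extrema(surfs[0])
        assert ex.argmax[:2] == (0.0, 100.0)  # carb vertex
        assert ex.argmin[:2] == (100.0, 0.0)  # protein vertex

    def test_empty_cluster_skipped(self, design):
        values = pd.DataFrame(
            [np.ones(57)], index=["f0"], columns=design.sample_ids
        )
        with pytest.warns(UserWarning, match="no members"):
            surfs = cluster_surface(
                {"f0": 0, "ghost": 1}, values, design, make_grid(resolution=25)
            )
        assert 1 not in surfs
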