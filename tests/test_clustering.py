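"""Fuzzifier estimate, fuzzy c-means correctness, elbow selection, assignment."""

import math

import numpy as np
import pandas as pd
import pytest
from sklearn.cluster import KMeans

from saltomics.clustering import (
    ClusterModel,
    assign_clusters,
    estimate_fuzzifier,
    fuzzy_cmeans,
    select_cluster_count,
    standardize_profiles,
)
from saltomics.errors import ValidationError


class TestFuzzifier:
    def test_published_value(self):
        """3831 profiles over 4 time points give the published m = 2.53."""
        assert round(estimate_fuzzifier(3831, 4), 2) == 2.53

    def test_three_dimensional_value(self):
        # independent evaluation of the closed form: 3.6416
        assert estimate_fuzzifier(3831, 3) == pytest.approx(3.6416, abs=5e-4)

    def test_matches_closed_form_on_grid(self):
        for n in (10, 100, 1000, 3831, 50000):
            for d in (2, 3, 4, 8, 16):
                expected = (
                    1
                    + (1418 / n + 22.05) * d**-2
                    + (12.33 / n + 0.243) * d ** (-0.0406 * math.log(n) - 0.1134)
                )
                assert abs(estimate_fuzzifier(n, d) - expected) < 1e-12

    def test_monotone_in_dimension(self):
        values = [estimate_fuzzifier(3831, d) for d in range(1, 20)]
        assert all(a > b for a, b in zip(values, values[1:]))
        assert all(v > 1 for v in values)

    def test_domain_errors(self):
        with pytest.raises(ValidationError):
            estimate_fuzzifier(1, 4)
        with pytest.raises(ValidationError):
            estimate_fuzzifier(100, 0)


class TestStandardize:
    def test_row_mean_zero_sd_one(self):
        df = pd.DataFrame([[1.0, 2.0, 3.0, 4.0]], index=["f"])
        z = standardize_profiles(df)
        assert z.loc["f"].mean() == pytest.approx(0, abs=1e-12)
        assert np.std(z.loc["f"]) == pytest.approx(1, abs=1e-12)

    def test_constant_row_excluded(self):
        df = pd.DataFrame([[5.0, 5.0, 5.0, 5.0], [1, 2, 3, 4]], index=["c", "v"])
        z = standardize_profiles(df)
        assert list(z.index) == ["v"]

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.normal(size=(10, 4)))
        z1 = standardize_profiles(df)
        z2 = standardize_profiles(z1)
        np.testing.assert_allclose(z1.to_numpy(), z2.to_numpy(), atol=1e-12)

    def test_all_constant_rejected(self):
        with pytest.raises(ValidationError):
            standardize_profiles(pd.DataFrame([[1.0, 1.0, 1.0]]))


def fcm_reference(X, c, m, v0, n_iter=300, tol=1e-9):
    """Naive loop implementation of the same update rules (test oracle)."""
    X = np.asarray(X, float)
    n, d = X.shape
    v = np.array(v0, float)
    u = np.zeros((n, c))
    for _ in range(n_iter + 1):
        for i in range(n):
            dists = [sum((X[i, j] - v[k, j]) ** 2 for j in range(d)) for k in range(c)]
            if min(dists) == 0.0:
                u[i] = 0.0
                u[i][dists.index(0.0)] = 1.0
                continue
            for k in range(c):
                u[i, k] = 1.0 / sum(
                    (dists[k] / dists[l]) ** (1.0 / (m - 1.0)) for l in range(c)
                )
        v_new = np.zeros_like(v)
        for k in range(c):
            w = u[:, k] ** m
            v_new[k] = (w[:, None] * X).sum(axis=0) / w.sum()
        if np.abs(v_new - v).max() < tol:
            v = v_new
            break
        v = v_new
    return u, v


def two_blobs(rng, n=40, sep=8.0, sd=0.3):
    a = rng.normal([0.0, 0.0], sd, size=(n, 2))
    b = rng.normal([sep, 0.0], sd, size=(n, 2))
    return np.vstack([a, b])


class TestFuzzyCMeans:
    def test_memberships_sum_to_one(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(60, 4))
        model = fuzzy_cmeans(X, 3, 2.0, seed=2, n_init=2)
        sums = model.memberships.to_numpy().sum(axis=1)
        np.testing.assert_allclose(sums, 1.0, atol=1e-9)

    def test_objective_non_increasing_over_random_data(self):
        rng = np.random.default_rng(3)
        for _ in range(15):
            X = rng.normal(size=(rng.integers(20, 60), rng.integers(2, 5)))
            model = fuzzy_cmeans(X, int(rng.integers(2, 5)), 2.0, seed=rng, n_init=1)
            J = model.objective_path
            assert (np.diff(J) <= 1e-9 * np.maximum(J[:-1], 1)).all()

    def test_point_at_centroid_gets_full_membership(self):
        X = np.array([[0.0, 0.0], [10.0, 0.0], [10.0, 0.1], [0.0, 0.1], [0.0, 0.05]])
        model = fuzzy_cmeans(X, 2, 2.0, seed=0, init_centroids=X[[0, 1]])
        d = np.linalg.norm(X[:, None] - model.centroids[None], axis=2)
        coincide = np.isclose(d.min(axis=1), 0.0)
        if coincide.any():
            u = model.memberships.to_numpy()
            assert np.allclose(u[coincide].max(axis=1), 1.0)

    def test_two_separated_groups_high_membership(self):
        rng = np.random.default_rng(4)
        X = two_blobs(rng)
        model = fuzzy_cmeans(X, 2, 2.0, seed=4)
        u = model.memberships.to_numpy()
        assert (u.max(axis=1) > 0.9).all()

    def test_agrees_with_reference_implementation(self):
        """Vectorized FCM matches an independently coded loop version."""
        rng = np.random.default_rng(5)
        for trial in range(10):
            n = int(rng.integers(20, 100))
            d = int(rng.integers(2, 5))
            c = int(rng.integers(2, 5))
            X = rng.normal(size=(n, d))
            v0 = X[rng.choice(n, c, replace=False)]
            model = fuzzy_cmeans(X, c, 2.0, init_centroids=v0, tol=1e-12, max_iter=500)
            u_ref, _ = fcm_reference(X, c, 2.0, v0, n_iter=500, tol=1e-12)
            assert np.abs(model.memberships.to_numpy() - u_ref).max() < 1e-6

    def test_kmeans_limit(self):
        """At m -> 1 on separated data FCM hardens to the k-means solution."""
        rng = np.random.default_rng(6)
        X = two_blobs(rng)
        v0 = X[[0, 40]]
        model = fuzzy_cmeans(X, 2, 1.05, init_centroids=v0)
        u = model.memberships.to_numpy()
        assert (u.max(axis=1) > 0.99).all()
        km = KMeans(n_clusters=2, init=v0, n_init=1).fit(X)
        hard = u.argmax(axis=1)
        # same partition up to label permutation
        agree = max((hard == km.labels_).mean(), (hard == 1 - km.labels_).mean())
        assert agree == 1.0

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(30, 3))
        perm = rng.permutation(30)
        v0 = X[:4]
        m1 = fuzzy_cmeans(X, 4, 2.0, init_centroids=v0)
        m2 = fuzzy_cmeans(X[perm], 4, 2.0, init_centroids=v0)
        np.testing.assert_allclose(
            m1.memberships.to_numpy()[perm], m2.memberships.to_numpy(), atol=1e-9
        )

    def test_c_ge_n_rejected(self):
        with pytest.raises(ValidationError):
            fuzzy_cmeans(np.zeros((3, 2)), 3, 2.0)


class TestSelectClusterCount:
    def test_two_groups_recovered(self):
        rng = np.random.default_rng(8)
        X = two_blobs(rng, n=100)
        c, curve = select_cluster_count(X, 1.5, range(2, 8), seed=8)
        assert c == 2

    def test_four_archetypes_recovered(self):
        rng = np.random.default_rng(9)
        centers = np.array(
            [[2, 1, 0], [0, 1, 2], [-2, -1, 0], [0, -1, -2]], dtype=float
        )
        X = np.vstack([rng.normal(mu, 0.25, size=(80, 3)) for mu in centers])
        c, _ = select_cluster_count(X, 1.8, range(2, 9), seed=9)
        assert c == 4

    def test_featureless_blob_falls_back(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(150, 3))
        with pytest.warns(UserWarning, match="no pronounced elbow"):
            c, _ = select_cluster_count(X, 2.0, range(2, 8), seed=10)
        assert c == 2

    def test_too_few_candidates_rejected(self):
        with pytest.raises(ValidationError):
            select_cluster_count(np.zeros((10, 2)), 2.0, range(2, 4), seed=0)


def model_with_memberships(u, centroids):
    u = np.asarray(u, float)
    return ClusterModel(
        c=u.shape[1], m=2.0, centroids=np.asarray(centroids, float),
        memberships=pd.DataFrame(u, columns=[f"u_{k+1}" for k in range(u.shape[1])]),
        objective=0.0, objective_path=np.zeros(1), converged=True,
    )


class TestAssignClusters:
    # centroids: clusters 1+2 induced, 3+4 repressed
    CENTROIDS = [[0, 2, 1, 0], [0, 1, 2, 0.5], [0, -2, -1, 0], [0, -1, -2, -0.5]]

    def test_clear_argmax(self):
        m = model_with_memberships([[0.7, 0.1, 0.1, 0.1]], self.CENTROIDS)
        assert assign_clusters(m).tolist() == [0]

    def test_combined_membership_rescue(self):
        # 0.35 + 0.30 = 0.65 > 0.6 over the induced pair -> argmax cluster 1
        m = model_with_memberships([[0.35, 0.30, 0.20, 0.15]], self.CENTROIDS)
        assert assign_clusters(m).tolist() == [0]

    def test_below_both_gates_unassigned(self):
        m = model_with_memberships([[0.30, 0.25, 0.25, 0.20]], self.CENTROIDS)
        assert assign_clusters(m).isna().tolist() == [True]

    def test_direction_labels(self):
        m = model_with_memberships([[1, 0, 0, 0]], self.CENTROIDS)
        assert m.direction == ("induced", "induced", "repressed", "repressed")
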