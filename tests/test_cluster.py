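"""PCA reduction, silhouette, Lloyd KMeans, k-selection and stability."""

import numpy as np
import pytest

from cdr3vec.cluster import (DegenerateDataError, KScanRecord, elbow_k,
                             fit_pca, kfold_stability, kmeans, scan_k,
                             select_k, silhouette)


def brute_force_silhouette(X, labels):
    """Literal per-point O(N^2) silhouette with the same conventions."""
    n = len(X)
    vals = []
    for i in range(n):
        own = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not own:
            vals.append(0.0)
            continue
        a = np.mean([np.linalg.norm(X[i] - X[j]) for j in own])
        b = min(np.mean([np.linalg.norm(X[i] - X[j])
                         for j in range(n) if labels[j] == lab])
                for lab in set(labels) if lab != labels[i])
        vals.append(0.0 if max(a, b) == 0 else (b - a) / max(a, b))
    return float(np.mean(vals))


class TestPCA:
    def test_collinear_data_needs_one_component(self, rng):
        X = np.column_stack([rng.normal(size=50), np.zeros(50)])
        model, scores = fit_pca(X, 0.9)
        assert model.n_retained == 1
        assert model.explained_variance_ratio[0] == pytest.approx(1.0)
        assert scores.shape == (50, 1)

    def test_full_threshold_keeps_rank(self, rng):
        X = rng.normal(size=(30, 6))
        model, _ = fit_pca(X, 1.0)
        assert model.n_retained == min(30 - 1, 6)
        assert model.explained_variance_ratio.sum() == pytest.approx(1.0)

    def test_isotropic_cloud_keeps_all_dimensions(self, rng):
        X = rng.normal(size=(1000, 5))
        model, _ = fit_pca(X, 0.9)
        assert model.n_retained == 5
        # each direction explains roughly a fifth of the variance
        assert np.all(model.explained_variance_ratio > 0.15)

    def test_components_orthonormal(self, rng):
        X = rng.normal(size=(40, 8)) @ rng.normal(size=(8, 8))
        model, _ = fit_pca(X, 0.9)
        C = model.components
        assert np.allclose(C @ C.T, np.eye(len(C)), atol=1e-8)

    def test_full_reconstruction_and_variance_conservation(self, rng):
        X = rng.normal(size=(25, 6)) * rng.uniform(0.1, 5, size=6)
        model, _ = fit_pca(X, 1.0)
        full_scores = model.transform(X, n_components=len(model.components))
        assert np.allclose(model.reconstruct(full_scores), X, atol=1e-8)
        assert full_scores.var(axis=0, ddof=1).sum() == pytest.approx(
            (X - X.mean(axis=0)).var(axis=0, ddof=1).sum())

    def test_ratios_non_increasing(self, rng):
        X = rng.normal(size=(60, 10)) * rng.uniform(0.1, 3, size=10)
        model, _ = fit_pca(X, 0.9)
        r = model.explained_variance_ratio
        assert np.all(np.diff(r) <= 1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateDataError):
            fit_pca(np.ones((10, 3)), 0.9)


class TestSilhouette:
    def test_two_tight_line_clusters(self):
        X = np.array([[0.0], [1.0], [100.0], [101.0]])
        labels = np.array([0, 0, 1, 1])
        # outer points: a=1, b=100.5; inner points: a=1, b=99.5
        expected = (99.5 / 100.5 + 98.5 / 99.5) / 2
        assert silhouette(X, labels) == pytest.approx(expected, abs=1e-10)

    def test_coincident_points_score_zero(self):
        X = np.zeros((6, 2))
        assert silhouette(X, np.array([0, 0, 0, 1, 1, 1])) == 0.0

    def test_singletons_score_zero(self):
        X = np.array([[0.0], [10.0]])
        assert silhouette(X, np.array([0, 1])) == 0.0

    def test_random_labels_near_zero(self, rng):
        X = rng.normal(size=(500, 3))
        labels = rng.integers(0, 3, 500)
        assert abs(silhouette(X, labels)) < 0.1

    def test_matches_brute_force(self, rng):
        for _ in range(15):
            n = int(rng.integers(10, 60))
            X = rng.normal(size=(n, 2))
            labels = rng.integers(0, int(rng.integers(2, 5)), n)
            if len(np.unique(labels)) < 2:
                continue
            assert silhouette(X, labels) == pytest.approx(
                brute_force_silhouette(X, labels), abs=1e-10)

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError):
            silhouette(np.zeros((4, 1)), np.zeros(4, dtype=int))


class TestKMeans:
    def test_exact_fit_when_k_equals_points(self):
        X = np.array([[0.0, 0], [5, 0], [0, 5], [5, 5]])
        res = kmeans(X, 4, seed=0)
        assert res.inertia == pytest.approx(0.0)
        assert sorted(map(tuple, res.centroids)) == sorted(map(tuple, X))

    def test_identical_points_single_cluster(self):
        X = np.ones((8, 2)) * 3.5
        res = kmeans(X, 1, seed=0)
        assert np.allclose(res.centroids[0], 3.5)
        assert res.inertia == pytest.approx(0.0)

    def test_two_blobs_recovered_exactly(self, rng):
        X = np.vstack([rng.normal((0, 0), 0.1, (30, 2)),
                       rng.normal((10, 0), 0.1, (30, 2))])
        res = kmeans(X, 2, seed=1)
        labels = res.labels
        assert len(set(labels[:30])) == 1 and len(set(labels[30:])) == 1
        assert labels[0] != labels[-1]

    def test_inertia_trace_monotone_nonincreasing(self, rng):
        X = rng.normal(size=(200, 4))
        for k in (2, 5, 8):
            res = kmeans(X, k, seed=3)
            trace = np.array(res.inertia_trace)
            assert np.all(np.diff(trace) <= 1e-9)

    def test_fixed_point_invariants(self, rng):
        from scipy.spatial.distance import cdist
        X = rng.normal(size=(120, 3))
        res = kmeans(X, 4, seed=5)
        d2 = cdist(X, res.centroids, "sqeuclidean")
        assert np.array_equal(d2.argmin(axis=1), res.labels)
        for j in range(4):
            assert np.allclose(res.centroids[j], X[res.labels == j].mean(axis=0))
        assert res.inertia == pytest.approx(
            d2[np.arange(len(X)), res.labels].sum())

    def test_deterministic_given_seed(self, rng):
        X = rng.normal(size=(80, 2))
        a = kmeans(X, 3, seed=9)
        b = kmeans(X, 3, seed=9)
        assert np.array_equal(a.labels, b.labels)
        assert a.inertia == b.inertia

    def test_matches_sklearn_on_separated_data(self, blobs):
        from sklearn.cluster import KMeans as SkKMeans
        X, _ = blobs
        mine = kmeans(X, 3, seed=0)
        ref = SkKMeans(3, n_init=10, random_state=0).fit(X)
        assert mine.inertia == pytest.approx(ref.inertia_, rel=1e-9)

    @pytest.mark.parametrize("k", [0, 11])
    def test_invalid_k_rejected(self, k):
        with pytest.raises(ValueError):
            kmeans(np.zeros((10, 2)), k)


class TestKSelection:
    def test_scan_recovers_three_blobs(self, blobs):
        X, _ = blobs
        scan = scan_k(X, 2, 8, seed=0)
        k, rule = select_k(scan)
        assert k == 3 and rule == "silhouette"
        inertias = [scan.inertias[k] for k in scan.k_values]
        assert np.all(np.diff(inertias) <= 1e-9)

    def test_scan_bounds_validated(self, blobs):
        X, _ = blobs
        with pytest.raises(ValueError):
            scan_k(X, 5, 4)
        with pytest.raises(ValueError):
            scan_k(X, 2, len(X) + 1)

    def _record(self, sils, inertias=None):
        ks = sorted(sils)
        if inertias is None:
            inertias = {k: 100.0 / k for k in ks}
        return KScanRecord(k_values=ks, inertias=inertias, silhouettes=sils)

    def test_interior_maximum_wins_regardless_of_guard(self):
        sils = {k: 0.1 for k in range(2, 16)}
        sils[9] = 0.42
        k, rule = select_k(self._record(sils), trivial_guard=True)
        assert (k, rule) == (9, "silhouette")

    def test_guard_off_accepts_k_min(self):
        sils = {2: 0.60, 3: 0.41, 4: 0.30, 5: 0.20}
        k, rule = select_k(self._record(sils), trivial_guard=False)
        assert (k, rule) == (2, "silhouette")

    def test_guard_on_falls_back_to_elbow(self):
        sils = {k: 0.6 - 0.05 * k for k in range(2, 10)}
        inertias = {2: 100, 3: 50, 4: 25, 5: 24, 6: 23, 7: 22, 8: 21, 9: 20}
        k, rule = select_k(self._record(sils, inertias), trivial_guard=True)
        assert rule == "elbow_fallback"
        assert k == 4   # knee of the constructed inertia curve

    def test_manual_override_wins(self):
        sils = {2: 0.9, 3: 0.1}
        k, rule = select_k(self._record(sils), manual_k=3)
        assert (k, rule) == (3, "manual")


class TestElbow:
    def test_knee_by_chord_distance(self):
        assert elbow_k({1: 100, 2: 50, 3: 25, 4: 24, 5: 23}) == 3

    def test_linear_curve_warns_and_returns_k_min(self):
        with pytest.warns(UserWarning, match="no knee"):
            assert elbow_k({2: 100, 3: 80, 4: 60, 5: 40}) == 2

    def test_two_points_rejected(self):
        with pytest.raises(ValueError):
            elbow_k({2: 10, 3: 5})


class TestKFoldStability:
    def test_validation_matches_full_data_silhouette(self, blobs):
        X, _ = blobs
        full = silhouette(X, kmeans(X, 3, seed=0).labels)
        scores, mean = kfold_stability(X, 3, n_folds=4, seed=0)
        assert len(scores) == 4
        assert mean == pytest.approx(full, abs=0.05)

    def test_leave_one_out_uses_zero_convention(self):
        X = np.array([[0.0], [0.1], [5.0], [5.1], [10.0], [10.1]])
        scores, _ = kfold_stability(X, 2, n_folds=6, seed=0)
        assert scores == [0.0] * 6   # singleton validation folds

    def test_deterministic_given_seed(self, blobs):
        X, _ = blobs
        assert kfold_stability(X, 3, 5, seed=2) == kfold_stability(X, 3, 5, seed=2)

    def test_fold_too_small_rejected(self):
        X = np.arange(8, dtype=float).reshape(-1, 1)
        with pytest.raises(ValueError):
            kfold_stability(X, 5, n_folds=2, seed=0)
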