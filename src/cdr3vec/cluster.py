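"""Dimensionality reduction and clustering of CDR3 embeddings.

The pipeline reduces the d-dimensional sequence embeddings with PCA,
keeping the smallest number of components whose cumulative explained
variance reaches a threshold (default 90%), then scans KMeans over
k = 2..15 and selects k by the maximum mean silhouette — unless that
maximum sits at the smallest k scanned, which is treated as a trivial
two-way split and replaced by the elbow (knee) of the inertia curve.

KMeans is Lloyd's algorithm from k-means++ starts, best of ``n_init``
restarts by inertia, with the per-iteration inertia trace kept on the
result so the monotone-descent property can be checked. Distances are
Euclidean throughout, consistent with centroid inertia and with the
downstream dispersion statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.cluster import kmeans_plusplus
from sklearn.decomposition import PCA
from sklearn.model_selection import KFold


class DegenerateDataError(ValueError):
    """Input carries no usable variance/structure for the operation."""


# ---------------------------------------------------------------------------
# PCA

@dataclass
class PCAModel:
    """Fitted PCA: mean, all components (orthonormal rows), variance ratios,
    and the number of components retained for the threshold used."""

    mean: np.ndarray
    components: np.ndarray              # p×d, all components
    explained_variance_ratio: np.ndarray
    n_retained: int

    def transform(self, X: np.ndarray, n_components: int | None = None) -> np.ndarray:
        L = self.n_retained if n_components is None else n_components
        return (np.asarray(X) - self.mean) @ self.components[:L].T

    def reconstruct(self, scores: np.ndarray) -> np.ndarray:
        """Map scores back to the original space (exact when all components used)."""
        L = scores.shape[1]
        return scores @ self.components[:L] + self.mean


def fit_pca(X: np.ndarray, var_threshold: float = 0.90) -> tuple[PCAModel, np.ndarray]:
    """Fit PCA and keep the fewest components reaching ``var_threshold``
    cumulative explained variance.

    Returns the model and the N×L score matrix. Zero-variance input is an
    error — there is nothing to retain.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 rows")
    if not np.isfinite(X).all():
        raise ValueError("matrix contains non-finite values")
    if not 0 < var_threshold <= 1:
        raise ValueError("var_threshold must be in (0, 1]")
    if np.allclose(X.var(axis=0), 0):
        raise DegenerateDataError("data has zero variance; nothing to retain")
    pca = PCA(n_components=None, svd_solver="full")
    scores_full = pca.fit_transform(X)
    ratios = pca.explained_variance_ratio_
    L = int(np.searchsorted(np.cumsum(ratios), var_threshold - 1e-12) + 1)
    L = min(L, len(ratios))
    model = PCAModel(mean=pca.mean_, components=pca.components_,
                     explained_variance_ratio=ratios, n_retained=L)
    return model, scores_full[:, :L]


# ---------------------------------------------------------------------------
# Silhouette

def silhouette(X: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette s(i) = (b-a)/max(a,b) over all points.

    a(i) is the mean distance to the other members of i's cluster, b(i)
    the smallest mean distance to another cluster. Conventions: a
    singleton scores 0; coincident data with a=b=0 scores 0.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    n = len(X)
    uniq, inv = np.unique(labels, return_inverse=True)
    k = len(uniq)
    if k < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    if k > n:
        raise ValueError("more clusters than points")
    D = cdist(X, X)
    # per-point sum of distances to each cluster
    sums = np.zeros((n, k))
    counts = np.bincount(inv, minlength=k)
    for j in range(k):
        sums[:, j] = D[:, inv == j].sum(axis=1)
    own = counts[inv]
    with np.errstate(invalid="ignore", divide="ignore"):
        a = sums[np.arange(n), inv] / np.maximum(own - 1, 1)
        mean_other = sums / counts[None, :]
        mean_other[np.arange(n), inv] = np.inf
        b = mean_other.min(axis=1)
        denom = np.maximum(a, b)
        s = np.where(denom > 0, (b - a) / np.where(denom > 0, denom, 1.0), 0.0)
    s[own == 1] = 0.0   # singleton convention
    return float(s.mean())


# ---------------------------------------------------------------------------
# KMeans

@dataclass
class ClusteringResult:
    labels: np.ndarray
    centroids: np.ndarray
    inertia: float
    k: int
    seed: int
    n_iter: int
    inertia_trace: list[float] = field(default_factory=list)


def _lloyd(X: np.ndarray, centers: np.ndarray, max_iter: int, tol: float):
    """Lloyd iterations from given centers; returns labels, centers, trace."""
    n, k = len(X), len(centers)
    trace: list[float] = []
    labels_prev = None
    stop_after_assign = False
    for _ in range(max_iter):
        d2 = cdist(X, centers, "sqeuclidean")
        labels = d2.argmin(axis=1)
        trace.append(float(d2[np.arange(n), labels].sum()))
        if stop_after_assign:
            break
        if labels_prev is not None and np.array_equal(labels, labels_prev):
            break
        new_centers = np.empty_like(centers)
        shift = 0.0
        point_d2 = d2[np.arange(n), labels]
        for j in range(k):
            mask = labels == j
            if mask.any():
                new_centers[j] = X[mask].mean(axis=0)
            else:
                # empty-cluster repair: reseed to the farthest point
                far = int(point_d2.argmax())
                new_centers[j] = X[far]
                point_d2[far] = 0.0
            shift += float(((new_centers[j] - centers[j]) ** 2).sum())
        centers = new_centers
        labels_prev = labels
        if tol > 0 and shift <= tol:
            # near-converged: take one final assignment pass, then stop
            stop_after_assign = True
    return labels, centers, trace


def kmeans(X: np.ndarray, k: int, seed: int = 0, n_init: int = 10,
           max_iter: int = 300, tol: float = 0.0) -> ClusteringResult:
    """KMeans: k-means++ starts, Lloyd descent, best of ``n_init`` by inertia.

    On return the labels are a fixed point (each point assigned to its
    nearest centroid) and each centroid is the mean of its assigned
    points; ``inertia_trace`` records the assignment-step inertia of the
    winning restart, which is non-increasing.
    """
    X = np.asarray(X, dtype=float)
    n = len(X)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of points ({n})")
    if not np.isfinite(X).all():
        raise ValueError("matrix contains non-finite values")
    states = np.random.SeedSequence(seed).generate_state(n_init) % (2 ** 31)
    best: ClusteringResult | None = None
    for r in range(n_init):
        if k == 1:
            centers = X.mean(axis=0, keepdims=True)
        else:
            centers, _ = kmeans_plusplus(X, n_clusters=k,
                                         random_state=int(states[r]))
        labels, centers, trace = _lloyd(X, centers, max_iter, tol)
        result = ClusteringResult(labels=labels, centroids=centers,
                                  inertia=trace[-1], k=k, seed=seed,
                                  n_iter=len(trace), inertia_trace=trace)
        if best is None or result.inertia < best.inertia:
            best = result
    return best


# ---------------------------------------------------------------------------
# k selection

@dataclass
class KScanRecord:
    """Inertia and silhouette curves over a k range, plus the selection."""

    k_values: list[int]
    inertias: dict[int, float]
    silhouettes: dict[int, float]
    selected_k: int | None = None
    selection_rule: str | None = None
    no_knee: bool = False


def scan_k(X: np.ndarray, k_min: int = 2, k_max: int = 15, seed: int = 0,
           n_init: int = 10) -> KScanRecord:
    """Run kmeans and silhouette for each k in [k_min, k_max]."""
    X = np.asarray(X, dtype=float)
    if k_min > k_max:
        raise ValueError(f"k_min={k_min} exceeds k_max={k_max}")
    if k_min < 2:
        raise ValueError("k_min must be >= 2 (silhouette is undefined below)")
    if k_max > len(X):
        raise ValueError(f"k_max={k_max} exceeds the number of points ({len(X)})")
    ks = list(range(k_min, k_max + 1))
    inertias, sils = {}, {}
    for k in ks:
        res = kmeans(X, k, seed=seed, n_init=n_init)
        inertias[k] = res.inertia
        sils[k] = silhouette(X, res.labels)
    return KScanRecord(k_values=ks, inertias=inertias, silhouettes=sils)


def elbow_k(inertias: dict[int, float]) -> int:
    """Knee of the inertia curve: the k farthest (perpendicular) from the
    chord joining the curve's endpoints; ties go to the smaller k.

    A curve with no knee (collinear/monotone-linear decay) returns the
    smallest k with a warning.
    """
    ks = sorted(inertias)
    if len(ks) < 3:
        raise ValueError("elbow detection needs at least 3 points on the curve")
    x = np.array(ks, dtype=float)
    y = np.array([inertias[k] for k in ks], dtype=float)
    dx, dy = x[-1] - x[0], y[-1] - y[0]
    norm = np.hypot(dx, dy)
    # perpendicular distance of each interior point to the chord
    dist = np.abs(dx * (y - y[0]) - dy * (x - x[0])) / norm
    best = int(np.argmax(dist))
    if dist[best] <= 1e-12 * max(1.0, abs(y[0])):
        warnings.warn("inertia curve has no knee; returning smallest k")
        return ks[0]
    return ks[best]


def select_k(scan: KScanRecord, trivial_guard: bool = True,
             manual_k: int | None = None) -> tuple[int, str]:
    """Choose k from a scan: silhouette argmax, with a trivial-partition guard.

    If the silhouette maximum sits at the smallest k scanned and the guard
    is on, the partition is treated as trivial (the silhouette favours
    coarse splits) and the elbow of the inertia curve is used instead.
    A manual override always wins. The choice is recorded on the record.
    """
    if manual_k is not None:
        scan.selected_k, scan.selection_rule = manual_k, "manual"
        return manual_k, "manual"
    ks = scan.k_values
    sil_argmax = max(ks, key=lambda k: (scan.silhouettes[k], -k))
    if trivial_guard and sil_argmax == ks[0] and len(ks) >= 3:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            k = elbow_k(scan.inertias)
            scan.no_knee = any("no knee" in str(w.message) for w in caught)
        scan.selected_k, scan.selection_rule = k, "elbow_fallback"
        return k, "elbow_fallback"
    scan.selected_k, scan.selection_rule = sil_argmax, "silhouette"
    return sil_argmax, "silhouette"


# ---------------------------------------------------------------------------
# stability

def kfold_stability(X: np.ndarray, k: int, n_folds: int = 5,
                    seed: int = 0, n_init: int = 10) -> tuple[list[float], float]:
    """K-fold check of partition stability.

    Each fold fits kmeans on the training portion, assigns the held-out
    points to the nearest fitted centroid and scores the held-out
    silhouette. Degenerate validation folds (a single point, or all points
    landing in one cluster) score 0 by the singleton convention.
    """
    X = np.asarray(X, dtype=float)
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    scores = []
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed % (2 ** 31))
    for train_idx, val_idx in kf.split(X):
        if len(train_idx) < k:
            raise ValueError(f"training fold of {len(train_idx)} points "
                             f"cannot fit k={k} clusters")
        res = kmeans(X[train_idx], k, seed=seed, n_init=n_init)
        val = X[val_idx]
        val_labels = cdist(val, res.centroids, "sqeuclidean").argmin(axis=1)
        if len(val) < 2 or len(np.unique(val_labels)) < 2:
            scores.append(0.0)
        else:
            scores.append(silhouette(val, val_labels))
    return scores, float(np.mean(scores))
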