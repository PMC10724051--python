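"""Trajectory clustering of person-level bent-line parameter estimates.

The four posterior-median random effects (score at CP, pre-CP slope, post-CP
slope, CP age) are standardized to sample Z-scores so the CP's year units do
not dominate Euclidean distance, K-means is run for k = 2..kmax, the cluster
count is selected by the Calinski-Harabasz criterion, and clusters receive
severity-ordered labels (k = 3: steep / intermediate / minimal decline,
ranked by mean post-CP slope).

K-means here is Lloyd's algorithm with k-means++ restarts; the within-cluster
sum of squares is asserted non-increasing across iterations on every run.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA

__all__ = [
    "FeatureMatrix",
    "ClusterSolution",
    "TrajectoryClusterer",
    "standardize_features",
    "calinski_harabasz",
    "select_k",
    "kmeans_cluster",
    "order_clusters_by_severity",
    "pca_projection",
]

FEATURES = ("alpha1", "alpha2", "alpha3", "tau")
SEVERITY_3 = ("steep", "intermediate", "minimal")


@dataclass
class FeatureMatrix:
    """Standardized per-participant clustering features (mean 0, SD 1)."""

    participant_ids: list
    features: np.ndarray  # (n, 4)
    columns: tuple = FEATURES
    means: np.ndarray | None = None
    sds: np.ndarray | None = None


@dataclass
class ClusterSolution:
    k: int
    assignments: np.ndarray  # (n,) cluster indices
    centroids: np.ndarray  # (k, d) in feature space
    inertia: float
    ch_index: float | None = None
    severity_labels: dict | None = None  # cluster index -> label
    tie_broken: bool = False

    def labels_for(self, order: str = "index") -> np.ndarray:
        if self.severity_labels is None:
            raise ValueError("severity labels not assigned yet")
        return np.array([self.severity_labels[c] for c in self.assignments])


def standardize_features(person_params: pd.DataFrame) -> FeatureMatrix:
    """Column-wise (x - mean)/SD with sample SD (denominator n-1)."""
    df = person_params
    if "participant_id" in df.columns:
        df = df.set_index("participant_id")
    X = df.loc[:, list(FEATURES)].to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 participants to standardize")
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    for j, s in enumerate(sds):
        if s == 0:
            raise ValueError(f"feature column {FEATURES[j]!r} has zero variance")
    Z = (X - means) / sds
    return FeatureMatrix(list(df.index), Z, FEATURES, means, sds)


def calinski_harabasz(features: np.ndarray, assignments) -> float:
    """Calinski-Harabasz index [B/(k-1)] / [W/(n-k)].

    B is the size-weighted squared distance of centroids to the grand
    centroid; W the within-cluster squared distance to centroids.  A solution
    with W == 0 (e.g. all-singleton clusters) returns +inf.
    """
    X = np.asarray(features, dtype=float)
    labels = np.asarray(assignments)
    n = X.shape[0]
    uniq, counts = np.unique(labels, return_counts=True)
    k = uniq.size
    if not 2 <= k <= n:
        # k == n (all singletons) is admitted and yields the +inf sentinel
        raise ValueError(f"CH index defined for 2 <= k <= n-1, got k={k}, n={n}")
    grand = X.mean(axis=0)
    B = 0.0
    W = 0.0
    for c, nc in zip(uniq, counts):
        pts = X[labels == c]
        cen = pts.mean(axis=0)
        B += nc * float(((cen - grand) ** 2).sum())
        W += float(((pts - cen) ** 2).sum())
    if W == 0.0:
        return np.inf
    return (B / (k - 1)) / (W / (n - k))


# ---------------------------------------------------------------------------
# Lloyd's algorithm
# ---------------------------------------------------------------------------


def _kmeanspp_init(X: np.ndarray, k: int, rng) -> np.ndarray:
    n = X.shape[0]
    centers = np.empty((k, X.shape[1]))
    centers[0] = X[rng.integers(n)]
    d2 = ((X - centers[0]) ** 2).sum(1)
    for j in range(1, k):
        total = d2.sum()
        if total == 0:
            centers[j] = X[rng.integers(n)]
        else:
            centers[j] = X[rng.choice(n, p=d2 / total)]
        d2 = np.minimum(d2, ((X - centers[j]) ** 2).sum(1))
    return centers


def _lloyd(X: np.ndarray, k: int, rng, max_iter: int = 300):
    centers = _kmeanspp_init(X, k, rng)
    prev_obj = np.inf
    labels = None
    for _ in range(max_iter):
        d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(2)
        new_labels = d2.argmin(1)
        obj = float(d2[np.arange(X.shape[0]), new_labels].sum())
        # Lloyd's objective never increases between assignment steps
        assert obj <= prev_obj + 1e-9, "k-means objective increased"
        prev_obj = obj
        if labels is not None and np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for c in range(k):
            pts = X[labels == c]
            if len(pts) == 0:  # re-seed an empty cluster at the farthest point
                far = d2.min(1).argmax()
                centers[c] = X[far]
            else:
                centers[c] = pts.mean(0)
    d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(2)
    labels = d2.argmin(1)
    inertia = float(d2[np.arange(X.shape[0]), labels].sum())
    return centers, labels, inertia


def kmeans_cluster(
    features, k: int, seed=None, n_init: int = 25
) -> ClusterSolution:
    """Best-of-``n_init`` k-means++ Lloyd's runs by within-cluster SS."""
    X = features.features if isinstance(features, FeatureMatrix) else np.asarray(
        features, dtype=float
    )
    n = X.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds number of points n={n}")
    if k == 1:
        cen = X.mean(0, keepdims=True)
        inertia = float(((X - cen) ** 2).sum())
        return ClusterSolution(1, np.zeros(n, dtype=int), cen, inertia)
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_init):
        centers, labels, inertia = _lloyd(X, k, rng)
        if best is None or inertia < best[2]:
            best = (centers, labels, inertia)
    centers, labels, inertia = best
    ch = calinski_harabasz(X, labels) if 2 <= len(np.unique(labels)) <= n - 1 else None
    return ClusterSolution(k, labels, centers, inertia, ch)


def select_k(
    features, kmax: int = 10, seed=None, n_init: int = 25
) -> tuple[int, pd.DataFrame]:
    """Run K-means for k = 2..kmax and pick the CH-optimal cluster count."""
    X = features.features if isinstance(features, FeatureMatrix) else np.asarray(
        features, dtype=float
    )
    n = X.shape[0]
    if kmax < 2:
        raise ValueError("kmax must be >= 2")
    if kmax > n - 1:
        warnings.warn(f"kmax={kmax} truncated to n-1={n - 1}")
        kmax = n - 1
    rows = []
    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    ss = root.spawn(kmax - 1)
    for k, child in zip(range(2, kmax + 1), ss):
        sol = kmeans_cluster(X, k, seed=child, n_init=n_init)
        rows.append({"k": k, "ch_index": sol.ch_index, "inertia": sol.inertia})
    table = pd.DataFrame(rows)
    best_k = int(table.loc[table["ch_index"].idxmax(), "k"])
    return best_k, table


def order_clusters_by_severity(
    solution: ClusterSolution, person_params: pd.DataFrame
) -> ClusterSolution:
    """Label clusters from worst to best decline.

    Ranked by mean (unstandardized) post-CP slope, most negative first; ties
    broken by lower mean score-at-CP.  k = 3 maps to steep / intermediate /
    minimal; other k get severity_1 (worst) .. severity_k (best).
    """
    if solution.k < 2:
        raise ValueError("severity ordering needs k >= 2")
    df = person_params
    if "participant_id" in df.columns:
        df = df.set_index("participant_id")
    a3 = df["alpha3"].to_numpy(dtype=float)
    a1 = df["alpha1"].to_numpy(dtype=float)
    keys = []
    tie = False
    means3 = {}
    for c in range(solution.k):
        sel = solution.assignments == c
        means3[c] = a3[sel].mean()
        keys.append((means3[c], a1[sel].mean(), c))
    vals = sorted(means3.values())
    if any(abs(x - y) < 1e-12 for x, y in zip(vals, vals[1:])):
        tie = True
    order = [c for _, _, c in sorted(keys)]
    if solution.k == 3:
        names = SEVERITY_3
    else:
        names = tuple(f"severity_{i + 1}" for i in range(solution.k))
    labels = {c: names[rank] for rank, c in enumerate(order)}
    return replace(solution, severity_labels=labels, tie_broken=tie)


def pca_projection(features, n_components: int = 2):
    """Principal-component scores of the standardized features.

    Sign convention: each component's largest-magnitude loading is positive,
    making the projection deterministic across library versions.
    Returns (scores, explained_variance_ratio, components).
    """
    X = features.features if isinstance(features, FeatureMatrix) else np.asarray(
        features, dtype=float
    )
    if X.shape[0] < 2:
        raise ValueError("PCA needs at least 2 observations")
    n_components = min(n_components, min(X.shape))
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    comps = pca.components_.copy()
    for j in range(comps.shape[0]):
        lead = np.argmax(np.abs(comps[j]))
        if comps[j, lead] < 0:
            comps[j] *= -1
            scores[:, j] *= -1
    return scores, pca.explained_variance_ratio_.copy(), comps


class TrajectoryClusterer(BaseEstimator):
    """Standardize, select k by the CH criterion, cluster, label severity.

    Parameters
    ----------
    k : fixed cluster count, or None to select by Calinski-Harabasz.
    kmax : largest k considered when selecting.
    n_init : k-means++ restarts per k.
    random_state : seed for initialization.

    Fitted attributes: ``best_k_``, ``ch_by_k_``, ``labels_`` (cluster
    indices), ``severity_labels_`` (per-participant strings), ``centroids_``,
    ``feature_matrix_``, ``pca_scores_``, ``pca_explained_``.
    """

    def __init__(
        self,
        k: int | None = None,
        kmax: int = 10,
        n_init: int = 25,
        random_state: int | None = None,
    ):
        self.k = k
        self.kmax = kmax
        self.n_init = n_init
        self.random_state = random_state

    def fit(self, X, y=None):
        df = X if isinstance(X, pd.DataFrame) else pd.DataFrame(X, columns=FEATURES)
        fm = standardize_features(df)
        root = np.random.SeedSequence(self.random_state)
        sel_seed, fit_seed = root.spawn(2)
        if self.k is None:
            best_k, table = select_k(fm, self.kmax, seed=sel_seed, n_init=self.n_init)
        else:
            best_k, table = int(self.k), None
        sol = kmeans_cluster(fm, best_k, seed=fit_seed, n_init=self.n_init)
        if best_k >= 2:
            sol = order_clusters_by_severity(sol, df)
            self.severity_labels_ = sol.labels_for()
        else:
            self.severity_labels_ = np.array(["all"] * len(fm.participant_ids))
        scores, evr, comps = pca_projection(fm)
        self.feature_matrix_ = fm
        self.best_k_ = best_k
        self.ch_by_k_ = table
        self.solution_ = sol
        self.labels_ = sol.assignments
        self.centroids_ = sol.centroids
        self.ch_index_ = sol.ch_index
        self.pca_scores_ = scores
        self.pca_explained_ = evr
        self.pca_components_ = comps
        self.participants_ = fm.participant_ids
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_

    def results_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "participant_id": self.participants_,
                "cluster_index": self.labels_,
                "severity_label": self.severity_labels_,
            }
        )
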