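"""Internal cluster-validity indices.

Calinski-Harabasz, mean Silhouette and Davies-Bouldin are delegated to
scikit-learn. The Gap statistic (Tibshirani et al.) and S_Dbw (Halkidi &
Vazirgiannis) have no implementation in the installed stack and are
computed here from their original definitions.

Conventions for degenerate labelings: indices that require at least two
non-empty clusters return NaN for single-cluster labelings; silhouette
additionally requires fewer clusters than points; singleton clusters
contribute a silhouette of 0 (scikit-learn's convention, kept here).
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
from scipy.spatial.distance import cdist

__all__ = ["cluster_quality_metrics", "gap_statistic", "s_dbw_index", "QUALITY_METRICS"]

QUALITY_METRICS = ("calinski_harabasz", "silhouette", "davies_bouldin", "gap", "s_dbw")


def _within_dispersion(X: np.ndarray, labels: np.ndarray) -> float:
    """Pooled within-cluster sum of squared distances to centroids."""
    w = 0.0
    for k in np.unique(labels):
        pts = X[labels == k]
        w += float(((pts - pts.mean(axis=0)) ** 2).sum())
    return w


def gap_statistic(
    X: np.ndarray, labels: np.ndarray, seed: int = 0, n_reference: int = 10
) -> float:
    """Gap = mean_b log(W*_b) - log(W).

    W is the within-cluster dispersion of the observed labeling; each W*_b
    comes from k-means (same cluster count) on a reference dataset drawn
    uniformly over the per-feature bounding box of X.
    """
    from sklearn.cluster import KMeans

    X = np.asarray(X, dtype=float)
    k = len(np.unique(labels))
    w = _within_dispersion(X, labels)
    if w <= 0:
        return np.nan
    lo, hi = X.min(axis=0), X.max(axis=0)
    rng = np.random.default_rng(seed)
    logs = []
    for _ in range(n_reference):
        ref = rng.uniform(lo, hi, size=X.shape)
        km = KMeans(n_clusters=k, n_init=1, random_state=int(rng.integers(2**31)))
        ref_labels = km.fit_predict(ref)
        w_ref = _within_dispersion(ref, ref_labels)
        logs.append(np.log(w_ref) if w_ref > 0 else np.nan)
    return float(np.nanmean(logs) - np.log(w))


def s_dbw_index(X: np.ndarray, labels: np.ndarray) -> float:
    """S_Dbw = average scattering + inter-cluster density.

    Scattering compares per-cluster variance norms with the dataset's;
    the density term asks, for each cluster pair, whether the midpoint
    between centroids is denser than the centroids themselves (points are
    counted within a radius equal to the average cluster-variance norm).
    Lower values indicate compact, well-separated clusters.
    """
    X = np.asarray(X, dtype=float)
    uniq = np.unique(labels)
    k = len(uniq)
    if k < 2:
        return np.nan
    total_var_norm = float(np.linalg.norm(np.var(X, axis=0)))
    if total_var_norm == 0:
        return np.nan
    centroids = np.vstack([X[labels == c].mean(axis=0) for c in uniq])
    var_norms = np.array([np.linalg.norm(np.var(X[labels == c], axis=0)) for c in uniq])
    scat = float(var_norms.mean() / total_var_norm)
    stdev = float(np.sqrt(var_norms.sum()) / k)

    def density(point: np.ndarray, members: np.ndarray) -> int:
        if len(members) == 0 or stdev == 0:
            return 0
        d = cdist(members, point[None, :]).ravel()
        return int((d <= stdev).sum())

    dens = 0.0
    n_pairs = 0
    for i in range(k):
        for j in range(k):
            if i == j:
                continue
            members = X[(labels == uniq[i]) | (labels == uniq[j])]
            mid = (centroids[i] + centroids[j]) / 2.0
            denom = max(density(centroids[i], members), density(centroids[j], members))
            dens += (density(mid, members) / denom) if denom > 0 else 0.0
            n_pairs += 1
    dens_bw = dens / n_pairs if n_pairs else np.nan
    return float(scat + dens_bw)


def cluster_quality_metrics(
    X: np.ndarray, labels: np.ndarray, seed: int = 0, gap_references: int = 10
) -> Mapping[str, float]:
    """The five validity indices for one labeling, NaN where undefined."""
    from sklearn.metrics import (
        calinski_harabasz_score,
        davies_bouldin_score,
        silhouette_score,
    )

    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    n = len(X)
    k = len(np.unique(labels))
    out: dict[str, float] = {m: np.nan for m in QUALITY_METRICS}
    if k >= 2:
        if k <= n - 1:  # all-singleton labelings leave these indices undefined
            out["calinski_harabasz"] = float(calinski_harabasz_score(X, labels))
            out["davies_bouldin"] = float(davies_bouldin_score(X, labels))
            out["silhouette"] = float(silhouette_score(X, labels))
        out["s_dbw"] = s_dbw_index(X, labels)
        out["gap"] = gap_statistic(X, labels, seed=seed, n_reference=gap_references)
    return out
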